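#!/usr/bin/env python
"""Channel-schedule calibration against the published size/compute budget.

Searches doubling schedules first, then the broader space of non-decreasing
even schedules, and reports every candidate whose exact parameter total
rounds to the 0.24 M budget together with its measured MAC count at 256x256.
The winning schedule is hard-coded as the package default
(`defifnet.network.DEFAULT_CHANNELS` / `DEFAULT_BOTTLENECK`).

Usage:
    python scripts/calibrate_channels.py
"""

from defifnet.calibration import calibrate


def main() -> None:
    winner, matches = calibrate(verbose=True)
    if winner is None:
        print("no schedule matches both budgets; candidates matching the "
              "parameter budget are listed above")
        return
    print(f"\nselected schedule: channels={winner.channels} "
          f"bottleneck={winner.bottleneck}")
    print(f"  parameters: {winner.params} ({winner.params_m:.2f} M)")
    print(f"  MACs@256:   {winner.macs} ({winner.macs_g:.2f} G)")


if __name__ == "__main__":
    main()
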