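"""Independent straight-line oracles for the bespoke blocks.

Everything here is computed with plain numpy loops / explicit formulas, one
named intermediate per equation, never through the package's autodiff engine
or layer kit — so agreement with the block implementations is a genuine
cross-check.
"""

from __future__ import annotations

import numpy as np


def ref_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
             groups: int = 1) -> np.ndarray:
    """Loop-based stride-1 zero-padded 'same' correlation."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, Cout, H, W), dtype=np.float64)
    cpg_out = Cout // groups
    for n in range(B):
        for co in range(Cout):
            g = co // cpg_out
            ci0 = g * Cin_g
            for i in range(H):
                for j in range(W):
                    patch = xp[n, ci0:ci0 + Cin_g, i:i + k, j:j + k]
                    out[n, co, i, j] = np.sum(patch * w[co])
    if b is not None:
        out += b.reshape(1, Cout, 1, 1)
    return out


def ref_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def ref_shuffle_perm(C: int, groups: int) -> list[int]:
    """Channel order of reshape(g, C/g) -> transpose -> flatten, by enumeration."""
    order = []
    for col in range(C // groups):
        for row in range(groups):
            order.append(row * (C // groups) + col)
    return order


def fifconv_oracle(x: np.ndarray, p: dict) -> np.ndarray:
    """Step-by-step evaluation of the split/transform/gate/recombine operator.

    `p` maps names conv1_left, conv1_right, group_conv, inner_left,
    inner_right to (weight, bias) numpy pairs.
    """
    C = x.shape[1]
    half = C // 2
    X1, X2 = x[:, :half], x[:, half:]                      # Eq 1: tear
    X1 = ref_conv(X1, *p["conv1_left"])                    # Eq 2: lift halves
    X2 = ref_conv(X2, *p["conv1_right"])
    X1 = ref_conv(X1, *p["group_conv"], groups=2) \
        + ref_conv(X1, *p["inner_left"])                   # Eq 3
    X2 = X2 + ref_conv(X2, *p["inner_right"])              # Eq 4
    Ycat = np.concatenate([X1, X2], axis=1)                # Eq 5: merge ...
    gate = ref_sigmoid(Ycat.mean(axis=(2, 3), keepdims=True))
    Ygated = Ycat * gate                                   # ... gate ...
    Y1, Y2 = Ygated[:, :C], Ygated[:, C:]                  # ... tear again
    return Y1 + Y2                                         # Eq 6: recombine


def ref_group_norm(x: np.ndarray, groups: int, eps: float = 1e-5) -> np.ndarray:
    B, C, H, W = x.shape
    d = x.reshape(B, groups, C // groups, H, W).astype(np.float64)
    mean = d.mean(axis=(2, 3, 4), keepdims=True)
    var = d.var(axis=(2, 3, 4), keepdims=True)
    return ((d - mean) / np.sqrt(var + eps)).reshape(B, C, H, W)


def cfrm_oracle(x: np.ndarray, p: dict, gn_groups: int = 2) -> np.ndarray:
    """Line-by-line evaluation of the channel feature reconstruction module."""
    C = x.shape[1]
    half = C // 2
    X1, X2 = x[:, :half], x[:, half:]                                  # line 1
    gap = X1.mean(axis=(2, 3), keepdims=True)
    Y1 = X1 * ref_sigmoid(gap * p["w_gap"] + p["b_gap"])               # line 2
    gn = ref_group_norm(X2, gn_groups)
    Y2 = ref_conv(X2, *p["branch2_conv"], groups=2) \
        * ref_sigmoid(gn * p["w_gn"] + p["b_gn"])                      # line 3
    Y = np.concatenate([Y1, Y2], axis=1)                               # line 4
    B, C2, H, W = Y.shape                                              # line 5
    return Y.reshape(B, 2, -1, H, W).transpose(0, 2, 1, 3, 4).reshape(
        B, -1, H, W)                                                   # line 6


def ref_batch_norm(x: np.ndarray, gamma, beta, eps: float = 1e-5) -> np.ndarray:
    mean = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    xhat = (x - mean) / np.sqrt(var + eps)
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def _cbr(x, conv, bn):
    return np.maximum(ref_batch_norm(ref_conv(x, *conv), *bn), 0.0)


def mbgm_oracle(x: np.ndarray, p: dict) -> np.ndarray:
    """Entry conv, ghost pair, extra branch, residual fusion, exit conv."""
    Y = _cbr(x, p["entry"], p["entry_bn"])                 # Eq 7
    P = _cbr(Y, p["primary"], p["primary_bn"])
    Q = _cbr(P, p["secondary"], p["secondary_bn"])
    R = _cbr(P, p["branch"], p["branch_bn"])
    fused = np.concatenate([Q, P + R], axis=1)
    return _cbr(fused, p["exit"], p["exit_bn"])            # Eq 8


# -- parameter extraction helpers (read-only views of a built block) --------


def fif_params(block) -> dict:
    return {
        "conv1_left": (block.conv1_left.weight.data.astype(np.float64),
                       block.conv1_left.bias.data.astype(np.float64)),
        "conv1_right": (block.conv1_right.weight.data.astype(np.float64),
                        block.conv1_right.bias.data.astype(np.float64)),
        "group_conv": (block.group_conv.weight.data.astype(np.float64),
                       block.group_conv.bias.data.astype(np.float64)),
        "inner_left": (block.inner_left.weight.data.astype(np.float64),
                       block.inner_left.bias.data.astype(np.float64)),
        "inner_right": (block.inner_right.weight.data.astype(np.float64),
                        block.inner_right.bias.data.astype(np.float64)),
    }


def cfrm_params(block) -> dict:
    return {
        "w_gap": block.w_gap.data.astype(np.float64),
        "b_gap": block.b_gap.data.astype(np.float64),
        "w_gn": block.w_gn.data.astype(np.float64),
        "b_gn": block.b_gn.data.astype(np.float64),
        "branch2_conv": (block.branch2_conv.weight.data.astype(np.float64),
                         block.branch2_conv.bias.data.astype(np.float64)),
    }


def mbgm_params(block) -> dict:
    out = {}
    for name in ("entry", "primary", "secondary", "branch", "exit"):
        unit = getattr(block, name)
        out[name] = (unit.conv.weight.data.astype(np.float64),
                     unit.conv.bias.data.astype(np.float64))
        out[name + "_bn"] = (unit.bn.gamma.data.astype(np.float64),
                             unit.bn.beta.data.astype(np.float64))
    return out
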