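"""Independent brute-force GLCM oracle: explicit double loop over all pixel
pairs, building the co-occurrence matrix cell by cell.  Kept deliberately
naive and separate from the library implementation."""

import numpy as np


def brute_force_glcm_stats(window: np.ndarray, levels: int,
                           offset: tuple[int, int],
                           symmetric: bool = True) -> dict[str, float]:
    dx, dy = offset
    h, w = window.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                if np.isfinite(window[r, c]) and np.isfinite(window[r2, c2]):
                    i, j = int(window[r, c]), int(window[r2, c2])
                    P[i, j] += 1
                    if symmetric:
                        P[j, i] += 1
    total = P.sum()
    if total == 0:
        return {k: np.nan for k in
                ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")}
    P /= total
    lev = np.arange(levels, dtype=float)
    ii = np.repeat(lev, levels).reshape(levels, levels)
    jj = ii.T
    mu_i = (ii * P).sum()
    mu_j = (jj * P).sum()
    var_i = (((ii - mu_i) ** 2) * P).sum()
    var_j = (((jj - mu_j) ** 2) * P).sum()
    nz = P > 0
    sigma = np.sqrt(var_i * var_j)
    return {
        "MEA": (ii * P).sum(),
        "VAR": (((ii - mu_i) ** 2) * P).sum(),
        "HOM": (P / (1 + (ii - jj) ** 2)).sum(),
        "CON": (((ii - jj) ** 2) * P).sum(),
        "DIS": (np.abs(ii - jj) * P).sum(),
        "ENT": -(P[nz] * np.log(P[nz])).sum(),
        "SEC": (P ** 2).sum(),
        "COR": ((((ii - mu_i) * (jj - mu_j)) * P).sum() / sigma
                if sigma > 0 else 0.0),
    }
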