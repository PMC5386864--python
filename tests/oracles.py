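"""Independent brute-force oracles used by the tests.

Everything here is computed straight from dense normal equations or from
reference library implementations, deliberately not sharing code with the
package's own linear-model engine.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    r = y - X @ beta
    return float(r @ r)


def ols_fit(X: np.ndarray, y: np.ndarray):
    """(beta, se, t, p, rss, r2) from explicit normal equations."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    se = np.sqrt(np.diag(XtX_inv) * rss / df)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    tss = float(np.sum((y - y.mean()) ** 2))
    return beta, se, t, p, rss, 1 - rss / tss


def group_f_test(X0: np.ndarray, Z: np.ndarray, y: np.ndarray) -> float:
    """F-test p-value for adding columns Z to model X0 (rank-aware)."""
    X1 = np.column_stack([X0, Z])
    r0, r1 = np.linalg.matrix_rank(X0), np.linalg.matrix_rank(X1)
    k = r1 - r0
    if k == 0:
        return 1.0
    rss0, rss1 = ols_rss(X0, y), ols_rss(X1, y)
    df = len(y) - r1
    F = ((rss0 - rss1) / k) / (rss1 / df)
    return float(stats.f.sf(F, k, df))


def family_design(fam_codes: np.ndarray) -> np.ndarray:
    n_fam = fam_codes.max() + 1
    F = np.zeros((fam_codes.size, n_fam))
    F[np.arange(fam_codes.size), fam_codes] = 1.0
    return F


def nested_columns(dose: np.ndarray, fam_codes: np.ndarray) -> np.ndarray:
    cols = []
    for k in range(fam_codes.max() + 1):
        m = fam_codes == k
        if dose[m].std() > 0:
            c = np.zeros(dose.size)
            c[m] = dose[m]
            cols.append(c)
    return np.column_stack(cols) if cols else np.empty((dose.size, 0))


def nested_pvalue_bruteforce(
    y: np.ndarray, doses: np.ndarray, fam_codes: np.ndarray,
    base_idx: list[int], marker_idx: int,
) -> float:
    X0 = family_design(fam_codes)
    for j in base_idx:
        X0 = np.column_stack([X0, nested_columns(doses[:, j], fam_codes)])
    Z = nested_columns(doses[:, marker_idx], fam_codes)
    if Z.shape[1] == 0:
        return 1.0
    return group_f_test(X0, Z, y)


def forward_path_bruteforce(
    y: np.ndarray, doses: np.ndarray, fam_codes: np.ndarray,
    chroms: np.ndarray, pos: np.ndarray, threshold: float, max_qtl: int = 10,
) -> list[int]:
    """Exhaustive per-step forward scan with the same tie-break rules."""
    selected: list[int] = []
    while len(selected) < max_qtl:
        best = None
        for j in range(doses.shape[1]):
            if j in selected:
                continue
            skip = False
            for s in selected:
                a, b = doses[:, j], doses[:, s]
                if a.std() > 0 and b.std() > 0:
                    if abs(np.corrcoef(a, b)[0, 1]) >= 1 - 1e-12:
                        skip = True
            if skip or nested_columns(doses[:, j], fam_codes).shape[1] == 0:
                continue
            p = nested_pvalue_bruteforce(y, doses, fam_codes, selected, j)
            key = (p, chroms[j], pos[j], j)
            if best is None or key < best:
                best = key
        if best is None or best[0] >= threshold:
            break
        selected.append(best[3])
    return selected


def lod_bruteforce(
    y: np.ndarray, doses: np.ndarray, fam_codes: np.ndarray,
    other_idx: list[int], marker_idx: int,
) -> float:
    X0 = family_design(fam_codes)
    for j in other_idx:
        X0 = np.column_stack([X0, nested_columns(doses[:, j], fam_codes)])
    Z = nested_columns(doses[:, marker_idx], fam_codes)
    rss0 = ols_rss(X0, y)
    rss1 = ols_rss(np.column_stack([X0, Z]), y) if Z.shape[1] else rss0
    return (len(y) / 2.0) * np.log10(rss0 / rss1)


def msc_ab_oracle(x: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Two-parameter least squares x ~ a + b*m via explicit normal equations."""
    A = np.column_stack([np.ones_like(m), m])
    a, b = np.linalg.solve(A.T @ A, A.T @ x)
    return float(a), float(b)
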