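"""Joint-linkage QTL mapping across NIL families.

The mapping model treats the library as one experiment: entry means are
regressed on a family main effect plus marker effects *nested within
families*, so every donor family gets its own allele effect at each
selected marker.  Donor-allele dose is coded additively (B=0, H=0.5, D=1),
which makes a nested coefficient the homozygous-substitution effect of that
family's donor allele relative to the recurrent (B73) allele; negative
means the donor allele lowers the trait.

The scan proceeds exactly as in the classical joint stepwise protocol:

1. a genome-wide entry threshold is found by permutation — trait values are
   shuffled across lines within each family and the minimum nested-marker
   p-value over all markers is recorded per permutation; the threshold is
   the ``gwer`` quantile of those minima;
2. forward selection repeatedly adds the marker whose family-nested term has
   the smallest grouped F-test p-value, while that p-value stays below the
   threshold;
3. the final model is refit by OLS to give per-family effects, t-tests
   against the B73 baseline, and the total R-squared;
4. each QTL gets a conditional LOD profile over its chromosome (other QTL
   held fixed) and a 1-LOD-drop support interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._base import BaseEstimator
from .genmap import GeneticMap
from .simulate import NILGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "QTLModel",
    "QTLReport",
    "LODProfile",
    "encode_dosage",
    "nested_marker_pvalue",
    "genome_scan_pvalues",
    "GenomeScanEngine",
    "permutation_threshold",
    "permutation_minimum_pvalues",
    "forward_select",
    "fit_final_model",
    "lod_profile",
    "support_interval",
    "allelic_effect_table",
    "JointLinkageMapper",
]

_RANK_TOL = 1e-9
_DOSE = {"B": 0.0, "H": 0.5, "D": 1.0}


@dataclass
class DosageMatrix:
    """Line x marker donor-allele dose with family labels.

    ``dose`` holds 0 / 0.5 / 1 for B / H / D calls; imputed entries may be
    fractional (family-mean imputation).
    """

    dose: pd.DataFrame
    family: pd.Series
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if not self.dose.index.equals(self.family.index):
            raise ValueError("dose and family must share the same line index")
        if self.dose.isna().to_numpy().any():
            raise ValueError("dosage matrix contains missing values after imputation")

    @property
    def lines(self) -> pd.Index:
        return self.dose.index

    @property
    def markers(self) -> list[str]:
        return list(self.dose.columns)

    def subset(self, lines: pd.Index) -> "DosageMatrix":
        return DosageMatrix(
            dose=self.dose.loc[lines], family=self.family.loc[lines], gmap=self.gmap
        )


def encode_dosage(genos: NILGenotypes, impute: str = "family_mean") -> DosageMatrix:
    """Additive donor-dose coding of genotype calls, with imputation.

    impute : {"family_mean", "zero"}
        Missing calls are replaced by the family's mean dose at the marker
        (default) or by 0 (recurrent-parent assumption).  Markers missing in
        every line of every family are dropped with a warning.
    """
    dose = genos.calls.apply(lambda col: col.map(_DOSE)).astype(float)
    all_missing = dose.isna().all(axis=0)
    if all_missing.any():
        dropped = list(dose.columns[all_missing])
        logger.warning("dropping %d marker(s) with no calls: %s", len(dropped), dropped)
        dose = dose.loc[:, ~all_missing]
        gmap = GeneticMap(
            genos.gmap.table[~genos.gmap.table["marker"].isin(dropped)].reset_index(
                drop=True
            )
        )
    else:
        gmap = genos.gmap
    if dose.isna().to_numpy().any():
        if impute == "family_mean":
            dose = dose.groupby(genos.family, sort=False).transform(
                lambda c: c.fillna(c.mean())
            )
            dose = dose.fillna(0.0)  # families with no call at the marker
        elif impute == "zero":
            dose = dose.fillna(0.0)
        else:
            raise ValueError(f"unknown imputation strategy {impute!r}")
    return DosageMatrix(dose=dose, family=genos.family.copy(), gmap=gmap)


# ---------------------------------------------------------------------------
# linear-model engine


def _align(y: pd.Series, dosage: DosageMatrix):
    """Complete-case alignment of a phenotype vector with the dosage matrix."""
    y = pd.Series(y).reindex(dosage.lines)
    keep = y.notna().to_numpy()
    sub = dosage.subset(dosage.lines[keep])
    fam_codes, fam_labels = pd.factorize(sub.family)
    return y.to_numpy(dtype=float)[keep], sub, fam_codes, list(fam_labels)


def _family_design(fam_codes: np.ndarray, n_fam: int) -> np.ndarray:
    F = np.zeros((fam_codes.size, n_fam))
    F[np.arange(fam_codes.size), fam_codes] = 1.0
    return F


def _nested_block(dose: np.ndarray, fam_codes: np.ndarray, n_fam: int):
    """Family-nested dose columns for the families where the marker segregates."""
    cols, fams = [], []
    for k in range(n_fam):
        mask = fam_codes == k
        d = dose[mask]
        if d.size and d.std() > 0:
            col = np.zeros(dose.size)
            col[mask] = d
            cols.append(col)
            fams.append(k)
    if not cols:
        return np.empty((dose.size, 0)), []
    return np.column_stack(cols), fams


def _orth_basis(A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, SVD-based)."""
    if A.size == 0 or A.shape[1] == 0:
        return np.empty((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((A.shape[0], 0))
    rank = int(np.sum(s > _RANK_TOL * s[0] * max(A.shape)))
    return U[:, :rank]


def _residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if Q.shape[1] == 0:
        return A
    return A - Q @ (Q.T @ A)


def _group_f_pvalue(rss0: float, rss1: float, k: int, df_resid: int) -> float:
    if k == 0:
        return 1.0
    if df_resid <= 0:
        return float("nan")
    num = max(rss0 - rss1, 0.0) / k
    den = max(rss1, 0.0) / df_resid
    if den == 0.0:
        return 0.0
    return float(stats.f.sf(num / den, k, df_resid))


def _blocks_for(markers, dose_values, marker_index, fam_codes, n_fam):
    out = []
    for m in markers:
        Z, fams = _nested_block(dose_values[:, marker_index[m]], fam_codes, n_fam)
        out.append((m, Z, fams))
    return out


class _Scan:
    """Shared state for one trait: aligned response, dosage and family design."""

    def __init__(self, y: pd.Series, dosage: DosageMatrix):
        self.y, self.dosage, self.fam_codes, self.fam_labels = _align(y, dosage)
        self.n = self.y.size
        self.n_fam = len(self.fam_labels)
        self.dose_values = self.dosage.dose.to_numpy(dtype=float)
        self.markers = self.dosage.markers
        self.marker_index = {m: j for j, m in enumerate(self.markers)}
        self.F = _family_design(self.fam_codes, self.n_fam)
        chrom_pos = self.dosage.gmap.table.set_index("marker")
        self.chrom = chrom_pos["chrom"].to_dict()
        self.pos = chrom_pos["pos_cm"].to_dict()

    def model_basis(self, markers: list[str]) -> np.ndarray:
        """Orthonormal basis of family design plus the markers' nested blocks."""
        parts = [self.F]
        for _, Z, _ in _blocks_for(
            markers, self.dose_values, self.marker_index, self.fam_codes, self.n_fam
        ):
            parts.append(Z)
        return _orth_basis(np.column_stack(parts))

    def add_marker_pvalue(self, Q: np.ndarray, marker: str) -> tuple[float, int]:
        """Grouped F-test p-value for adding one marker's nested term.

        Returns (p, k) where k is the retained numerator df.  A marker that
        segregates in no family returns (1.0, 0).
        """
        Z, fams = _nested_block(
            self.dose_values[:, self.marker_index[marker]], self.fam_codes, self.n_fam
        )
        if not fams:
            return 1.0, 0
        G = _orth_basis(_residualize(Z, Q))
        k = G.shape[1]
        if k == 0:
            return 1.0, 0
        yr = _residualize(self.y[:, None], Q)[:, 0]
        rss0 = float(yr @ yr)
        proj = G.T @ yr
        rss1 = rss0 - float(proj @ proj)
        p0 = Q.shape[1]
        return _group_f_pvalue(rss0, rss1, k, self.n - p0 - k), k


def nested_marker_pvalue(
    y: pd.Series,
    dosage: DosageMatrix,
    marker: str,
    base_markers=(),
) -> float:
    """Grouped F-test p-value for adding a marker's family-nested term.

    ``base_markers`` is the set of markers already in the model (a fitted
    ``QTLModel`` is also accepted); the base model always contains the
    family main effects.  A marker segregating in no family returns 1.0.
    """
    if isinstance(base_markers, QTLModel):
        base_markers = base_markers.markers
    base_markers = list(base_markers)
    if marker in base_markers:
        raise ValueError(f"marker {marker!r} already in the base model")
    scan = _Scan(y, dosage)
    Q = scan.model_basis(base_markers)
    p, k = scan.add_marker_pvalue(Q, marker)
    if k == 0:
        logger.warning("marker %r segregates in no family; p-value set to 1", marker)
    return p


# ---------------------------------------------------------------------------
# permutation threshold


def permutation_threshold(
    y: pd.Series,
    dosage: DosageMatrix,
    n_perm: int = 1000,
    gwer: float = 0.05,
    seed: int = 0,
) -> float:
    """Permutation genome-wide entry threshold on the p-value scale.

    Trait values are shuffled across lines within each family (genotypes
    fixed), the minimum nested-marker p-value against the family-only model
    is recorded per permutation, and the ``gwer`` quantile of the minima is
    returned.  Controls the probability of declaring any QTL on null data at
    approximately ``gwer``.
    """
    if not 0.0 < gwer < 1.0:
        raise ValueError("gwer must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    minima = permutation_minimum_pvalues(y, dosage, n_perm, seed)
    return float(np.quantile(minima, gwer))


class GenomeScanEngine:
    """Precomputed per-marker bases for fast repeated genome scans.

    Builds, once per dosage matrix, the orthonormal bases of every marker's
    family-nested columns residualized against the family main effects.
    Scans of different response vectors (observed or permuted) then reduce
    to one matrix product, which makes permutation thresholds and
    many-dataset null simulations cheap.
    """

    def __init__(self, dosage: DosageMatrix):
        self.dosage = dosage
        fam_codes, fam_labels = pd.factorize(dosage.family)
        self.fam_codes, self.fam_labels = fam_codes, list(fam_labels)
        self.n = len(dosage.lines)
        self.n_fam = len(self.fam_labels)
        self.markers = dosage.markers
        dose_values = dosage.dose.to_numpy(dtype=float)
        self.QF = _orth_basis(_family_design(fam_codes, self.n_fam))
        bases, slices, dfs = [], [], []
        start = 0
        for j, _ in enumerate(self.markers):
            Z, fams = _nested_block(dose_values[:, j], fam_codes, self.n_fam)
            G = (
                _orth_basis(_residualize(Z, self.QF))
                if fams
                else np.empty((self.n, 0))
            )
            k = G.shape[1]
            bases.append(G)
            slices.append((start, start + k))
            dfs.append(k)
            start += k
        self.G_all = np.hstack(bases) if start else np.empty((self.n, 0))
        self.slices, self.dfs = slices, dfs
        self.fam_groups = [np.flatnonzero(fam_codes == k) for k in range(self.n_fam)]

    def _align_y(self, y: pd.Series) -> np.ndarray:
        y = pd.Series(y).reindex(self.dosage.lines).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(
                "engine scans require complete phenotypes; subset the dosage "
                "matrix to complete-case lines first"
            )
        return y

    def scan_columns(self, Y: np.ndarray) -> np.ndarray:
        """Per-marker grouped-F p-values for each column of family-residualized Y."""
        n_col = Y.shape[1]
        rss0 = np.sum(Y**2, axis=0)
        proj = self.G_all.T @ Y if self.G_all.shape[1] else np.empty((0, n_col))
        p0 = self.QF.shape[1]
        out = np.ones((len(self.markers), n_col))
        for i, ((a, b), k) in enumerate(zip(self.slices, self.dfs)):
            if k == 0:
                continue
            ssq = np.sum(proj[a:b, :] ** 2, axis=0)
            rss1 = np.maximum(rss0 - ssq, 0.0)
            df_resid = self.n - p0 - k
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ssq / k) / (rss1 / df_resid)
            pv = stats.f.sf(F, k, df_resid)
            out[i] = np.where(rss1 <= 0, 0.0, pv)
        return out

    def scan(self, y: pd.Series) -> pd.Series:
        """Genome scan of one response against the family-only base model."""
        yr = _residualize(self._align_y(y)[:, None], self.QF)
        return pd.Series(self.scan_columns(yr)[:, 0], index=self.markers)

    def permutation_minima(
        self, y: pd.Series, n_perm: int, seed: int = 0
    ) -> np.ndarray:
        """Minimum scan p-value for each within-family permutation of y."""
        rng = np.random.default_rng(seed)
        yr = _residualize(self._align_y(y)[:, None], self.QF)[:, 0]
        Yp = np.empty((self.n, n_perm))
        for j in range(n_perm):
            col = np.empty(self.n)
            for idx in self.fam_groups:
                col[idx] = yr[rng.permutation(idx)]
            Yp[:, j] = col
        return self.scan_columns(Yp).min(axis=0)

    def threshold(self, y: pd.Series, n_perm: int, gwer: float, seed: int = 0) -> float:
        return float(np.quantile(self.permutation_minima(y, n_perm, seed), gwer))


def genome_scan_pvalues(y: pd.Series, dosage: DosageMatrix) -> pd.Series:
    """Per-marker nested-term p-values against the family-only model."""
    y = pd.Series(y).reindex(dosage.lines)
    keep = y.notna()
    sub = dosage.subset(dosage.lines[keep.to_numpy()])
    return GenomeScanEngine(sub).scan(y[keep])


def permutation_minimum_pvalues(
    y: pd.Series, dosage: DosageMatrix, n_perm: int, seed: int = 0
) -> np.ndarray:
    """Minimum genome-scan p-value for each within-family permutation."""
    y = pd.Series(y).reindex(dosage.lines)
    keep = y.notna()
    sub = dosage.subset(dosage.lines[keep.to_numpy()])
    return GenomeScanEngine(sub).permutation_minima(y[keep], n_perm, seed)


# ---------------------------------------------------------------------------
# forward selection and the final model


@dataclass
class QTLModel:
    """Fitted joint-linkage model for one trait."""

    trait: str | None
    markers: list[str]
    coef: pd.DataFrame  # term, marker, family, estimate, se, t, p
    r2: float
    rss: float
    n: int
    df_resid: int
    threshold: float | None = None
    selection: pd.DataFrame | None = None  # marker, p_enter, step

    def family_effects(self) -> pd.DataFrame:
        return self.coef[self.coef["term"] == "family"].reset_index(drop=True)

    def marker_effects(self, marker: str | None = None) -> pd.DataFrame:
        sel = self.coef["term"] == "marker"
        if marker is not None:
            sel &= self.coef["marker"] == marker
        return self.coef[sel].reset_index(drop=True)


def _tie_key(scan: _Scan, marker: str):
    return (scan.chrom[marker], scan.pos[marker], marker)


def forward_select(
    y: pd.Series,
    dosage: DosageMatrix,
    threshold: float,
    max_qtl: int | None = None,
    trait: str | None = None,
) -> QTLModel:
    """Forward stepwise selection of family-nested marker terms.

    Starting from the family-main-effects-only model, the marker with the
    smallest grouped F-test p-value is added while that p-value is below
    ``threshold``.  Ties are broken by chromosome then cM position; markers
    whose dose vector is perfectly correlated with an already-selected
    marker are skipped.  Returns the OLS refit of the selected model.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    scan = _Scan(y, dosage)
    selected: list[str] = []
    records = []
    Q = scan.model_basis(selected)
    while max_qtl is None or len(selected) < max_qtl:
        best = None
        for m in scan.markers:
            if m in selected:
                continue
            dm = scan.dose_values[:, scan.marker_index[m]]
            if any(
                abs(_safe_corr(dm, scan.dose_values[:, scan.marker_index[s]])) >= 1.0 - 1e-12
                for s in selected
            ):
                continue
            p, k = scan.add_marker_pvalue(Q, m)
            if k == 0:
                continue
            key = (p, *_tie_key(scan, m))
            if best is None or key < best[0]:
                best = (key, m, p)
        if best is None or best[2] >= threshold:
            break
        selected.append(best[1])
        records.append({"step": len(selected), "marker": best[1], "p_enter": best[2]})
        Q = scan.model_basis(selected)
    model = fit_final_model(y, dosage, selected, trait=trait)
    model.threshold = threshold
    model.selection = pd.DataFrame(records, columns=["step", "marker", "p_enter"])
    return model


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_final_model(
    y: pd.Series,
    dosage: DosageMatrix,
    markers: list[str],
    trait: str | None = None,
) -> QTLModel:
    """OLS fit of family main effects plus all selected nested marker terms.

    Per-coefficient two-sided t-tests compare each family's donor allele to
    the recurrent-parent (0-dose) baseline.  Rank-deficient columns are
    dropped with a log message.
    """
    scan = _Scan(y, dosage)
    names: list[tuple[str, str | None, str | None]] = [("intercept", None, None)]
    cols = [np.ones(scan.n)]
    for k in range(1, scan.n_fam):  # treatment-coded family effects
        names.append(("family", None, scan.fam_labels[k]))
        cols.append((scan.fam_codes == k).astype(float))
    for m, Z, fams in _blocks_for(
        markers, scan.dose_values, scan.marker_index, scan.fam_codes, scan.n_fam
    ):
        for j, kf in enumerate(fams):
            names.append(("marker", m, scan.fam_labels[kf]))
            cols.append(Z[:, j])
    X = np.column_stack(cols)

    # rank filter: keep the earliest independent columns
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.info("dropping %d rank-deficient column(s): %s", len(dropped), dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ scan.y)
    resid = scan.y - X @ beta
    rss = float(resid @ resid)
    df_resid = scan.n - X.shape[1]
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(np.sum((scan.y - scan.y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    coef = pd.DataFrame(
        {
            "term": [t for t, _, _ in names],
            "marker": [m for _, m, _ in names],
            "family": [f for _, _, f in names],
            "estimate": beta,
            "se": se,
            "t": tvals,
            "p": pvals,
        }
    )
    return QTLModel(
        trait=trait, markers=list(markers), coef=coef,
        r2=float(r2), rss=rss, n=scan.n, df_resid=df_resid,
    )


def _independent_columns(X: np.ndarray) -> list[int]:
    """Indices of a maximal independent set of columns, preferring early ones."""
    keep: list[int] = []
    Q = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        r = _residualize(X[:, [j]], Q)
        norm = np.linalg.norm(r)
        if norm > _RANK_TOL * max(np.linalg.norm(X[:, j]), 1.0):
            keep.append(j)
            Q = np.hstack([Q, r / norm])
    return keep


# ---------------------------------------------------------------------------
# LOD profiles, support intervals, allelic effect report


@dataclass
class LODProfile:
    """Conditional LOD curve over one chromosome for one fitted QTL."""

    trait: str | None
    qtl_marker: str
    chrom: int
    table: pd.DataFrame  # marker, pos_cm, lod
    degenerate: bool = False  # single-marker chromosome

    @property
    def peak_marker(self) -> str:
        return str(self.table.loc[self.table["lod"].idxmax(), "marker"])


def lod_profile(
    y: pd.Series, dosage: DosageMatrix, model: QTLModel, qtl_marker: str
) -> LODProfile:
    """Rescan one QTL's chromosome with all other selected QTL held fixed.

    For each marker m on the chromosome, the profiled QTL's nested columns
    are replaced by m's nested columns and LOD(m) = (n/2) * log10(RSS_0 /
    RSS_m), where RSS_0 is from the model with no marker in this slot.
    """
    if qtl_marker not in model.markers:
        raise ValueError(f"marker {qtl_marker!r} is not part of the fitted model")
    scan = _Scan(y, dosage)
    chrom = scan.chrom[qtl_marker]
    others = [m for m in model.markers if m != qtl_marker]
    Q = scan.model_basis(others)
    yr = _residualize(scan.y[:, None], Q)[:, 0]
    rss0 = float(yr @ yr)
    rows = []
    chrom_markers = [m for m in scan.markers if scan.chrom[m] == chrom]
    for m in chrom_markers:
        Z, fams = _nested_block(
            scan.dose_values[:, scan.marker_index[m]], scan.fam_codes, scan.n_fam
        )
        if fams:
            G = _orth_basis(_residualize(Z, Q))
            proj = G.T @ yr
            rss1 = max(rss0 - float(proj @ proj), np.finfo(float).tiny)
        else:
            rss1 = rss0
        lod = (scan.n / 2.0) * np.log10(rss0 / rss1)
        rows.append({"marker": m, "pos_cm": scan.pos[m], "lod": lod})
    degenerate = len(chrom_markers) == 1
    if degenerate:
        logger.warning(
            "chromosome %d has a single marker; LOD profile is degenerate", chrom
        )
    return LODProfile(
        trait=model.trait, qtl_marker=qtl_marker, chrom=chrom,
        table=pd.DataFrame(rows), degenerate=degenerate,
    )


def support_interval(profile: LODProfile, drop: float = 1.0) -> tuple[float, float]:
    """1-LOD-drop support interval (cM) around the profile peak.

    Walks outward from the peak while markers stay within ``drop`` LOD units
    of the peak; returns the cM positions of the outermost such markers.
    """
    t = profile.table
    if len(t) == 0:
        raise ValueError("empty LOD profile")
    lods = t["lod"].to_numpy()
    pos = t["pos_cm"].to_numpy()
    peak = int(np.argmax(lods))
    cut = lods[peak] - drop
    lo = peak
    while lo > 0 and lods[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(lods) - 1 and lods[hi + 1] >= cut:
        hi += 1
    return float(pos[lo]), float(pos[hi])


@dataclass
class QTLReport:
    """Tabular summary of one trait's QTL mirroring the standard reports."""

    trait: str | None
    threshold: float | None
    r2: float
    summary: pd.DataFrame       # marker, chrom, pos_cm, interval lo/hi, flanks
    effects: pd.DataFrame       # QTL x family, numeric effect (NaN where "-")
    pvalues: pd.DataFrame       # QTL x family
    stars: pd.DataFrame         # QTL x family, "", "*", "**" or "-"
    n_significant_positive: int = 0
    n_significant_negative: int = 0

    def formatted_effects(self) -> pd.DataFrame:
        out = self.effects.copy().astype(object)
        for i in self.effects.index:
            for j in self.effects.columns:
                star = self.stars.loc[i, j]
                if star == "-":
                    out.loc[i, j] = "-"
                else:
                    out.loc[i, j] = f"{self.effects.loc[i, j]:.3f}{star}"
        return out


def allelic_effect_table(
    model: QTLModel,
    dosage: DosageMatrix,
    y: pd.Series | None = None,
    intervals: dict[str, tuple[float, float]] | None = None,
) -> QTLReport:
    """Per-QTL, per-family allele effects with significance stars.

    A cell is "-" when the family carries no donor introgression (dose 0 in
    every line) at that marker, so no allele contrast exists.  Stars mark
    raw two-sided p < 0.05 (*) and p < 0.01 (**) from the final-model
    t-tests against the B73 baseline.
    """
    fam_labels = pd.unique(dosage.family).tolist()
    markers = model.markers
    effects = pd.DataFrame(np.nan, index=markers, columns=fam_labels)
    pvalues = pd.DataFrame(np.nan, index=markers, columns=fam_labels)
    stars = pd.DataFrame("", index=markers, columns=fam_labels, dtype=object)
    me = model.marker_effects()
    for _, row in me.iterrows():
        effects.loc[row["marker"], row["family"]] = row["estimate"]
        pvalues.loc[row["marker"], row["family"]] = row["p"]
        if row["p"] < 0.01:
            stars.loc[row["marker"], row["family"]] = "**"
        elif row["p"] < 0.05:
            stars.loc[row["marker"], row["family"]] = "*"
    for m in markers:
        dm = dosage.dose[m]
        for f in fam_labels:
            if dm[dosage.family == f].max() <= 0:
                stars.loc[m, f] = "-"
                effects.loc[m, f] = np.nan
                pvalues.loc[m, f] = np.nan

    sig = (pvalues < 0.05) & effects.notna()
    n_pos = int(((effects > 0) & sig).sum().sum())
    n_neg = int(((effects < 0) & sig).sum().sum())

    rows = []
    for m in markers:
        chrom, pos = dosage.gmap.marker_info(m)
        lo, hi = (intervals or {}).get(m, (np.nan, np.nan))
        rows.append(
            {
                "marker": m, "chrom": chrom, "pos_cm": pos,
                "interval_lo_cm": lo, "interval_hi_cm": hi,
                "n_families_no_introgression": int((stars.loc[m] == "-").sum()),
            }
        )
    return QTLReport(
        trait=model.trait, threshold=model.threshold, r2=model.r2,
        summary=pd.DataFrame(rows), effects=effects, pvalues=pvalues, stars=stars,
        n_significant_positive=n_pos, n_significant_negative=n_neg,
    )


# ---------------------------------------------------------------------------
# estimator facade


class JointLinkageMapper(BaseEstimator):
    """Joint-linkage QTL mapper with permutation entry threshold.

    A scikit-learn-style estimator: ``fit(X, y)`` takes a ``DosageMatrix``
    (or ``NILGenotypes``) and per-line entry means, runs the permutation
    threshold (unless ``threshold`` overrides it), forward selection and the
    final OLS refit, and exposes the results as fitted attributes.

    Parameters
    ----------
    n_perm : number of within-family permutations for the entry threshold.
    gwer : genome-wide error rate controlled by the threshold.
    threshold : explicit entry p-value threshold; skips the permutations.
    max_qtl : optional cap on the number of selected markers.
    seed : seed for the permutation generator.
    lod_drop : LOD-drop used for support intervals.
    impute : imputation strategy if fit is given raw genotype calls.

    Attributes (after fit)
    ----------------------
    threshold_ : entry threshold used.
    model_ : fitted :class:`QTLModel`.
    selected_markers_ : ordered list of selected markers.
    profiles_ : dict marker -> :class:`LODProfile`.
    intervals_ : dict marker -> (cM lo, cM hi) support interval.
    report_ : :class:`QTLReport`.
    r2_ : total variance explained by the final model.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        gwer: float = 0.05,
        threshold: float | None = None,
        max_qtl: int | None = None,
        seed: int = 0,
        lod_drop: float = 1.0,
        impute: str = "family_mean",
    ):
        self.n_perm = n_perm
        self.gwer = gwer
        self.threshold = threshold
        self.max_qtl = max_qtl
        self.seed = seed
        self.lod_drop = lod_drop
        self.impute = impute

    def fit(self, X, y, trait: str | None = None):
        dosage = (
            encode_dosage(X, impute=self.impute) if isinstance(X, NILGenotypes) else X
        )
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            self.threshold_ = permutation_threshold(
                y, dosage, n_perm=self.n_perm, gwer=self.gwer, seed=self.seed
            )
        self.model_ = forward_select(
            y, dosage, self.threshold_, max_qtl=self.max_qtl, trait=trait
        )
        self.selected_markers_ = list(self.model_.markers)
        self.profiles_ = {
            m: lod_profile(y, dosage, self.model_, m) for m in self.selected_markers_
        }
        self.intervals_ = {
            m: support_interval(p, self.lod_drop) for m, p in self.profiles_.items()
        }
        self.report_ = allelic_effect_table(
            self.model_, dosage, intervals=self.intervals_
        )
        self.r2_ = self.model_.r2
        self.dosage_ = dosage
        return self

    def predict(self, X=None) -> pd.Series:
        """Genetic prediction (family effect + selected QTL effects) per line."""
        self._check_is_fitted("model_")
        dosage = self.dosage_ if X is None else (
            encode_dosage(X, impute=self.impute) if isinstance(X, NILGenotypes) else X
        )
        coef = self.model_.coef
        pred = np.full(len(dosage.lines), float(
            coef.loc[coef["term"] == "intercept", "estimate"].iloc[0]
        ))
        fam = dosage.family.to_numpy()
        for _, row in coef.iterrows():
            if row["term"] == "family":
                pred += np.where(fam == row["family"], row["estimate"], 0.0)
            elif row["term"] == "marker":
                dm = dosage.dose[row["marker"]].to_numpy()
                pred += np.where(fam == row["family"], dm * row["estimate"], 0.0)
        return pd.Series(pred, index=dosage.lines, name="predicted")
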