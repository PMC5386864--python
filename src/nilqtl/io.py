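"""Readers and writers for the delimited file formats.

All tables are tab-delimited UTF-8 with a header row; missing values are
written as ``NA``.  Output files carry ``#``-prefixed header lines recording
the package version, the seed and the parameters that produced them;
readers skip such comment lines.  Formats:

genetic map      marker, chrom, pos_cm
genotypes        line, family, one column per marker with calls B/H/D/NA
plot table       line, env, rep, trait, value  (long format)
LSmeans          line, one column per trait
spectra          sample, one column per wavelength (nm)
reference        sample, trait, value
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genmap import GeneticMap
from .simulate import CALL_CODES, NILGenotypes
from .spectra import SpectraSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_genetic_map",
    "write_genetic_map",
    "read_genotypes",
    "write_genotypes",
    "read_plot_table",
    "write_plot_table",
    "read_lsmeans",
    "write_lsmeans",
    "read_spectra",
    "write_spectra",
    "read_reference_values",
    "write_reference_values",
    "write_table",
]

_NA = "NA"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such file")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", na_values=[_NA], keep_default_na=False,
            **kwargs,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    return df


def _header_lines(seed: int | None = None, **params) -> list[str]:
    items = [f"version={__version__}"]
    if seed is not None:
        items.append(f"seed={seed}")
    items.extend(f"{k}={v}" for k, v in params.items())
    return [f"# nilqtl {' '.join(items)}"]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    index: bool = False, **params,
) -> None:
    """Write any DataFrame as a commented, tab-delimited table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header_lines(seed=seed, **params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=_NA, index=index)


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = _read_tsv(path)
    expected = ["marker", "chrom", "pos_cm"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"{path}: malformed header, expected columns {expected}, "
            f"got {list(df.columns[:3])}"
        )
    for i, row in df.iterrows():
        try:
            int(row["chrom"])
            float(row["pos_cm"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: line {i + 2}: bad chrom/pos_cm "
                f"({row['chrom']!r}, {row['pos_cm']!r})"
            ) from None
    df = df.astype({"marker": str, "chrom": int, "pos_cm": float})
    try:
        return GeneticMap(df[expected])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_genetic_map(gmap: GeneticMap, path: str | Path, **params) -> None:
    write_table(gmap.table, path, **params)


def read_genotypes(path: str | Path, gmap: GeneticMap) -> NILGenotypes:
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["line", "family"]:
        raise ValueError(
            f"{path}: malformed header, first columns must be 'line', 'family'"
        )
    marker_cols = list(df.columns[2:])
    unknown = [m for m in marker_cols if m not in set(gmap.markers)]
    if unknown:
        raise ValueError(f"{path}: markers absent from the map: {unknown}")
    missing = [m for m in gmap.markers if m not in set(marker_cols)]
    if missing:
        raise ValueError(f"{path}: markers in the map but not in the file: {missing}")
    if df["line"].duplicated().any():
        dup = df.loc[df["line"].duplicated(), "line"].iloc[0]
        raise ValueError(f"{path}: duplicate line identifier {dup!r}")
    calls = df.set_index("line")[list(gmap.markers)]
    values = calls.to_numpy(dtype=object)
    bad = ~(pd.isna(values) | np.isin(values, CALL_CODES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {i + 2}: unknown genotype code {values[i, j]!r} "
            f"in field {calls.columns[j]!r}"
        )
    family = df.set_index("line")["family"]
    return NILGenotypes(calls=calls, family=family, gmap=gmap)


def write_genotypes(genos: NILGenotypes, path: str | Path, **params) -> None:
    out = pd.concat([genos.family, genos.calls], axis=1).reset_index()
    write_table(out, path, **params)


def read_plot_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    expected = ["line", "env", "rep", "trait", "value"]
    if list(df.columns[:5]) != expected:
        raise ValueError(f"{path}: malformed header, expected columns {expected}")
    dup = df.duplicated(subset=["line", "env", "rep", "trait"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: line {i + 2}: duplicate (line, env, rep, trait) key")
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric value field: {exc}") from None
    return df[expected].astype({"line": str, "env": str, "rep": str, "trait": str})


def write_plot_table(plots: pd.DataFrame, path: str | Path, **params) -> None:
    write_table(plots, path, **params)


def read_lsmeans(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "line":
        raise ValueError(f"{path}: malformed header, first column must be 'line'")
    if df["line"].duplicated().any():
        raise ValueError(f"{path}: duplicate line identifier")
    out = df.set_index("line")
    return out.astype(float)


def write_lsmeans(lsmeans: pd.DataFrame, path: str | Path, **params) -> None:
    write_table(lsmeans.reset_index(), path, **params)


def read_spectra(path: str | Path, reference: str | Path | None = None) -> SpectraSet:
    df = _read_tsv(path)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: malformed header, first column must be 'sample'")
    try:
        wl = [float(c) for c in df.columns[1:]]
    except ValueError:
        raise ValueError(f"{path}: non-numeric wavelength column label") from None
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"{path}: wavelength columns must be strictly increasing")
    absorb = df.set_index("sample").astype(float)
    ref = None
    if reference is not None:
        ref_long = read_reference_values(reference)
        ref = ref_long.pivot(index="sample", columns="trait", values="value")
        ref.columns.name = None
        ref = ref.reindex(absorb.index)
    try:
        return SpectraSet(absorbance=absorb, reference=ref)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_spectra(spectra: SpectraSet, path: str | Path, **params) -> None:
    write_table(spectra.absorbance.reset_index(), path, **params)


def read_reference_values(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    expected = ["sample", "trait", "value"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: malformed header, expected columns {expected}")
    df["value"] = df["value"].astype(float)
    return df[expected].astype({"sample": str, "trait": str})


def write_reference_values(reference: pd.DataFrame, path: str | Path, **params) -> None:
    """Write a sample x trait reference matrix in long (sample, trait, value) form."""
    long = reference.reset_index().melt(
        id_vars=reference.index.name or "index", var_name="trait", value_name="value"
    )
    long.columns = ["sample", "trait", "value"]
    write_table(long, path, **params)
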