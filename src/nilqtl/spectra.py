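"""Spectra container and synthetic kernel-spectra generation.

The synthetic generator emulates diffuse-reflectance NIR absorbance
(log(1/R)) of bulk intact kernels as Beer-Lambert mixtures of three latent
constituents (starch, protein, oil), plus multiplicative/additive scatter
and white noise.  Oil is concentrated in the embryo, so in intact-kernel
reflectance its observable signal depends on how many embryos face the
detector; the generator models this with a random per-sample attenuation of
the oil bands ("orientation noise"), which is what makes an NIR oil
calibration unreliable while protein and starch calibrate well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "make_kernel_spectra", "make_nmr_oil_data"]


@dataclass
class SpectraSet:
    """Sample x wavelength absorbance matrix with optional reference values.

    ``absorbance`` is a DataFrame indexed by sample ID whose columns are the
    wavelengths (nm, strictly increasing).  ``reference`` is an optional
    sample x trait DataFrame of reference chemistry (% dry matter).
    """

    absorbance: pd.DataFrame
    reference: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        wl = self.wavelengths
        if len(wl) == 0:
            raise ValueError("spectra set has no wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.isfinite(self.absorbance.to_numpy(dtype=float)).all():
            raise ValueError("absorbance matrix contains non-finite values")
        if self.reference is not None and not self.reference.index.equals(
            self.absorbance.index
        ):
            raise ValueError("reference values must be indexed by the same samples")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.absorbance.columns])

    @property
    def samples(self) -> pd.Index:
        return self.absorbance.index

    @property
    def values(self) -> np.ndarray:
        return self.absorbance.to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            absorbance=pd.DataFrame(
                values, index=self.absorbance.index, columns=self.absorbance.columns
            ),
            reference=self.reference,
        )

    def restrict(self, lo_nm: float, hi_nm: float) -> "SpectraSet":
        """Subset to the wavelength window [lo_nm, hi_nm]."""
        wl = self.wavelengths
        keep = (wl >= lo_nm) & (wl <= hi_nm)
        return SpectraSet(
            absorbance=self.absorbance.loc[:, self.absorbance.columns[keep]],
            reference=self.reference,
        )


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


# NIR band centers (nm) and widths for the three latent constituents —
# carbohydrate O-H/C-O combination bands for starch, amide N-H bands for
# protein, C-H stretch overtones for oil
_BANDS = {
    "starch": ((1450.0, 45.0, 0.8), (1930.0, 50.0, 1.0), (2100.0, 40.0, 0.9)),
    "protein": ((1510.0, 35.0, 0.7), (2055.0, 30.0, 1.0), (2180.0, 35.0, 0.9)),
    "oil": ((1210.0, 30.0, 0.7), (1725.0, 25.0, 1.0), (2310.0, 30.0, 0.9)),
}

#: reference-chemistry distributions (% dry matter): mean, sd, (lo, hi)
_REFERENCE_DIST = {
    "starch": (68.65, 5.40, (55.3, 82.3)),
    "protein": (12.91, 3.08, (6.8, 21.4)),
    "oil": (3.94, 1.42, (1.7, 6.3)),
}


def make_kernel_spectra(
    n_samples: int = 210,
    seed: int = 0,
    noise_sd: float = 0.003,
    scatter: bool = True,
    oil_orientation_sd: float = 0.35,
    lo_nm: float = 400.0,
    hi_nm: float = 2500.0,
    step_nm: float = 10.0,
) -> SpectraSet:
    """Synthetic intact-kernel NIR spectra with reference chemistry.

    Parameters
    ----------
    noise_sd : white spectral noise, absorbance units per channel.
    scatter : add per-sample multiplicative (sd 0.1) and additive (sd 0.05)
        scatter, removable by multiplicative scatter correction.
    oil_orientation_sd : sd of the random per-sample attenuation applied to
        the oil bands (log-normal, mean 1); 0 disables orientation noise.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm)
    conc = {}
    for trait, (mean, sd, (lo, hi)) in _REFERENCE_DIST.items():
        c = rng.normal(mean, sd, size=n_samples)
        conc[trait] = np.clip(c, lo, hi)

    pure = {
        trait: sum(a * _gauss(wl, c, w) for c, w, a in _BANDS[trait])
        for trait in _BANDS
    }
    baseline = 0.2 + 0.3 * (wl - wl[0]) / (wl[-1] - wl[0])

    X = np.tile(baseline, (n_samples, 1))
    for trait in _BANDS:
        weight = conc[trait][:, None] / 100.0
        if trait == "oil" and oil_orientation_sd > 0:
            attenuation = np.exp(
                rng.normal(-0.5 * oil_orientation_sd**2, oil_orientation_sd, n_samples)
            )
            weight = weight * attenuation[:, None]
        X = X + weight * pure[trait][None, :]
    if scatter:
        b = rng.normal(1.0, 0.1, size=n_samples)
        a = rng.normal(0.0, 0.05, size=n_samples)
        X = a[:, None] + b[:, None] * X
    X = X + rng.normal(0.0, noise_sd, size=X.shape)

    index = pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample")
    return SpectraSet(
        absorbance=pd.DataFrame(X, index=index, columns=[f"{w:g}" for w in wl]),
        reference=pd.DataFrame(conc, index=index),
    )


def make_nmr_oil_data(
    n_samples: int = 45,
    seed: int = 0,
    slope: float = 15.0,
    intercept: float = 2.0,
    replicate_sd: float = 1.0,
    sample_sd: float = 4.0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic NMR resonance readings (triplicate) with oil references.

    The mean resonance is linear in oil content; ``sample_sd`` is
    between-sample instrument noise (resonance units) and ``replicate_sd``
    within-sample repeatability.  Returns (resonance readings with one
    column per replicate, reference oil %).
    """
    rng = np.random.default_rng(seed)
    mean, sd, (lo, hi) = _REFERENCE_DIST["oil"]
    oil = np.clip(rng.normal(mean, sd, size=n_samples), lo, hi)
    true_signal = intercept + slope * oil + rng.normal(0.0, sample_sd, n_samples)
    readings = true_signal[:, None] + rng.normal(
        0.0, replicate_sd, size=(n_samples, n_replicates)
    )
    index = pd.Index([f"N{i + 1:03d}" for i in range(n_samples)], name="sample")
    resonance = pd.DataFrame(
        readings, index=index, columns=[f"rep{j + 1}" for j in range(n_replicates)]
    )
    return resonance, pd.Series(oil, index=index, name="oil")
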