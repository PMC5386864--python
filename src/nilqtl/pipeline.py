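"""End-to-end pipeline: simulate or load, calibrate, reduce, map, report.

The pipeline is driven by a YAML configuration (see :class:`PipelineConfig`)
and writes every stage's artifacts as commented, tab-delimited files whose
headers record the package version, master seed and stage parameters.
Stage seeds are derived deterministically from the master seed, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io
from .calibration import (
    MultiplicativeScatterCorrection,
    PLS1Regression,
    SavitzkyGolayDerivative,
)
from .genmap import GeneticMap, default_map
from .linkage import JointLinkageMapper, encode_dosage
from .phenotype import compute_lsmeans, estimate_heritability, phenotypic_correlations
from .simulate import (
    DEFAULT_VARIANCE_COMPONENTS,
    EnvSpec,
    PedigreeSpec,
    QTLSpec,
    default_family_sizes,
    simulate_nil_population,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``genotypes``/``phenotypes`` hold either a ``file`` entry (load) or a
    ``simulate`` entry (generate); ``calibration`` is optional.
    """

    seed: int = 0
    out_dir: str = "nilqtl_out"
    traits: list[str] = field(default_factory=lambda: ["starch", "protein", "oil"])
    map: dict[str, Any] = field(default_factory=dict)
    genotypes: dict[str, Any] = field(default_factory=lambda: {"simulate": {}})
    phenotypes: dict[str, Any] = field(default_factory=lambda: {"simulate": {}})
    mapping: dict[str, Any] = field(default_factory=dict)
    calibration: dict[str, Any] | None = None

    def validate(self) -> None:
        for key in ("genotypes", "phenotypes"):
            section = getattr(self, key)
            if "file" not in section and "simulate" not in section:
                raise ValueError(f"config section {key!r} needs 'file' or 'simulate'")
            if "file" in section and not Path(section["file"]).exists():
                raise ValueError(f"{key} file not found: {section['file']}")
        if "file" in self.map and not Path(self.map["file"]).exists():
            raise ValueError(f"map file not found: {self.map['file']}")
        if self.calibration:
            for key in ("spectra", "reference"):
                if key not in self.calibration:
                    raise ValueError(f"calibration section needs {key!r}")
                if not Path(self.calibration[key]).exists():
                    raise ValueError(
                        f"calibration {key} file not found: {self.calibration[key]}"
                    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _build_map(cfg: PipelineConfig) -> GeneticMap:
    if "file" in cfg.map:
        return io.read_genetic_map(cfg.map["file"])
    kwargs = {k: v for k, v in cfg.map.items() if k in ("n_markers",)}
    if "chrom_lengths" in cfg.map:
        kwargs["chrom_lengths"] = tuple(cfg.map["chrom_lengths"])
    return default_map(**kwargs)


def _build_qtl(spec_list: list[dict]) -> list[QTLSpec]:
    return [
        QTLSpec(marker=q["marker"], trait=q["trait"], effects=dict(q.get("effects", {})))
        for q in spec_list
    ]


def _env_for_trait(sim_cfg: dict, trait: str) -> EnvSpec:
    vc = sim_cfg.get("variance_components", {}).get(
        trait, DEFAULT_VARIANCE_COMPONENTS.get(trait, {})
    )
    return EnvSpec(
        n_env=sim_cfg.get("n_env", 2),
        n_rep=sim_cfg.get("n_rep", 2),
        env_effects=tuple(sim_cfg["env_effects"]) if "env_effects" in sim_cfg else None,
        sigma2_g=vc.get("sigma2_g", 1.0),
        sigma2_ge=vc.get("sigma2_ge", 0.25),
        sigma2_e=vc.get("sigma2_e", 0.5),
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns in-memory results per stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict[str, Any] = {"seed": config.seed}

    gmap = _build_map(config)
    io.write_genetic_map(gmap, out / "genetic_map.tsv", seed=config.seed)
    logger.info("map: %d markers on %d chromosomes (%.0f cM)",
                gmap.n_markers, len(gmap.chromosomes), gmap.total_length)

    # --- genotypes -------------------------------------------------------
    if "file" in config.genotypes:
        genos = io.read_genotypes(config.genotypes["file"], gmap)
    else:
        sim = config.genotypes.get("simulate", {}) or {}
        genos = simulate_nil_population(
            gmap,
            family_sizes=sim.get("family_sizes") or default_family_sizes(),
            pedigree=PedigreeSpec(
                n_backcross=sim.get("n_backcross", 4), n_self=sim.get("n_self", 2)
            ),
            seed=sim.get("seed", seeds[0]),
            missing_rate=sim.get("missing_rate", 0.0),
        )
        io.write_genotypes(genos, out / "genotypes.tsv", seed=config.seed)
    logger.info("genotypes: %d lines, %d families", len(genos.lines),
                len(genos.families))
    results["genotypes"] = genos

    # --- optional spectral calibration -----------------------------------
    if config.calibration:
        results["calibration"] = _run_calibration(config, out)

    # --- phenotypes ------------------------------------------------------
    if "file" in config.phenotypes:
        plots = io.read_plot_table(config.phenotypes["file"])
    else:
        sim = config.phenotypes.get("simulate", {}) or {}
        qtl = _build_qtl(sim.get("qtl", []))
        frames = []
        for i, trait in enumerate(config.traits):
            env = _env_for_trait(sim, trait)
            frames.append(
                simulate_phenotypes(
                    genos, [q for q in qtl if q.trait == trait], env,
                    seed=sim.get("seed", seeds[1]) + i, traits=[trait],
                )
            )
        plots = pd.concat(frames, ignore_index=True)
        io.write_plot_table(plots, out / "plots.tsv", seed=config.seed)
    results["plots"] = plots

    # --- entry means, heritability, correlations -------------------------
    lsmeans = compute_lsmeans(plots)
    io.write_lsmeans(lsmeans, out / "lsmeans.tsv", seed=config.seed)
    herit = estimate_heritability(plots)
    herit_df = pd.DataFrame([vars(h) for h in herit])
    io.write_table(herit_df, out / "heritability.tsv", seed=config.seed)
    for h in herit:
        logger.info("H2[%s] = %.3f (sG2=%.3f, sGE2=%.3f, se2=%.3f)",
                    h.trait, h.h2, h.sigma2_g, h.sigma2_ge, h.sigma2_e)
    corr = phenotypic_correlations(lsmeans)
    io.write_table(corr.r.reset_index(names="trait"), out / "correlations_r.tsv",
                   seed=config.seed)
    io.write_table(corr.p.reset_index(names="trait"), out / "correlations_p.tsv",
                   seed=config.seed)
    results.update(lsmeans=lsmeans, heritability=herit, correlations=corr)

    # --- joint-linkage mapping -------------------------------------------
    m = config.mapping
    dosage = encode_dosage(genos, impute=m.get("impute", "family_mean"))
    mappers: dict[str, JointLinkageMapper] = {}
    qtl_rows = []
    for i, trait in enumerate(config.traits):
        if trait not in lsmeans.columns:
            logger.warning("trait %r absent from LSmeans; skipped", trait)
            continue
        mapper = JointLinkageMapper(
            n_perm=m.get("n_perm", 1000),
            gwer=m.get("gwer", 0.05),
            threshold=m.get("threshold"),
            max_qtl=m.get("max_qtl"),
            seed=m.get("seed", seeds[2]) + i,
        ).fit(dosage, lsmeans[trait], trait=trait)
        mappers[trait] = mapper
        logger.info("map[%s]: threshold=%.3g, %d QTL, R2=%.3f", trait,
                    mapper.threshold_, len(mapper.selected_markers_), mapper.r2_)
        rep = mapper.report_
        io.write_table(
            rep.summary.assign(trait=trait), out / f"qtl_{trait}.tsv",
            seed=config.seed, threshold=f"{mapper.threshold_:.6g}",
            r2=f"{mapper.r2_:.4f}",
        )
        io.write_table(
            rep.formatted_effects().reset_index(names="marker"),
            out / f"effects_{trait}.tsv", seed=config.seed,
        )
        for marker, prof in mapper.profiles_.items():
            io.write_table(
                prof.table.assign(trait=trait, qtl=marker),
                out / f"lod_{trait}_{marker}.tsv", seed=config.seed,
            )
        for _, row in rep.summary.iterrows():
            qtl_rows.append(
                {
                    "trait": trait, "marker": row["marker"], "chrom": row["chrom"],
                    "pos_cm": row["pos_cm"], "interval_lo_cm": row["interval_lo_cm"],
                    "interval_hi_cm": row["interval_hi_cm"],
                    "threshold": mapper.threshold_, "model_r2": mapper.r2_,
                }
            )
    summary = pd.DataFrame(
        qtl_rows, columns=["trait", "marker", "chrom", "pos_cm", "interval_lo_cm",
                            "interval_hi_cm", "threshold", "model_r2"],
    )
    io.write_table(summary, out / "qtl_summary.tsv", seed=config.seed)
    results.update(mappers=mappers, qtl_summary=summary)
    return results


def _run_calibration(config: PipelineConfig, out: Path) -> dict[str, Any]:
    cal = config.calibration or {}
    spectra = io.read_spectra(cal["spectra"], reference=cal["reference"])
    if spectra.reference is None:
        raise ValueError("calibration requires reference values")
    chain_names = cal.get("preprocess", ["msc"])
    models: dict[str, Any] = {}
    rows = []
    for trait in cal.get("traits", list(spectra.reference.columns)):
        y = spectra.reference[trait].dropna()
        X = spectra.absorbance.loc[y.index]
        transformed = X.to_numpy(dtype=float)
        chain = []
        for name in chain_names:
            if name == "msc":
                step = MultiplicativeScatterCorrection()
            elif name in ("sg", "savgol", "sg1"):
                step = SavitzkyGolayDerivative(
                    window=cal.get("sg_window", 11),
                    polyorder=cal.get("sg_polyorder", 2),
                )
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
            transformed = step.fit_transform(transformed)
            chain.append(step)
        model = PLS1Regression(
            n_components=cal.get("components", "loo"),
            max_components=cal.get("max_components", 15),
        ).fit(transformed, y)
        st = model.training_stats_
        models[trait] = {"chain": chain, "model": model, "stats": st}
        rows.append(
            {"trait": trait, "preprocess": "+".join(chain_names),
             "n_components": model.n_components_, "r": st.r, "sec": st.sec,
             "n": st.n}
        )
        logger.info("calibration[%s]: %s", trait, st)
    io.write_table(pd.DataFrame(rows), out / "calibration_stats.tsv",
                   seed=config.seed)
    return models
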