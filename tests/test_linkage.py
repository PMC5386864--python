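"""Joint-linkage mapping: oracle equivalence, null behaviour, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from nilqtl.genmap import GeneticMap
from nilqtl.linkage import (
    DosageMatrix,
    GenomeScanEngine,
    JointLinkageMapper,
    LODProfile,
    allelic_effect_table,
    encode_dosage,
    fit_final_model,
    forward_select,
    genome_scan_pvalues,
    lod_profile,
    nested_marker_pvalue,
    permutation_threshold,
    support_interval,
)
from nilqtl.simulate import EnvSpec, NILGenotypes, QTLSpec, simulate_phenotypes
from nilqtl.phenotype import compute_lsmeans


def random_instance(seed, n_lines=40, n_markers=12, n_fam=3):
    """Small random dosage instance with realistic {0, 0.5, 1} doses."""
    rng = np.random.default_rng(seed)
    per_chrom = max(n_markers // 2, 1)
    rows = [
        (f"m{j}", 1 + j // per_chrom, 5.0 * (j % per_chrom))
        for j in range(n_markers)
    ]
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))
    doses = rng.choice([0.0, 0.5, 1.0], p=[0.7, 0.15, 0.15], size=(n_lines, n_markers))
    fam_codes = rng.integers(0, n_fam, size=n_lines)
    lines = pd.Index([f"L{i}" for i in range(n_lines)], name="line")
    dosage = DosageMatrix(
        dose=pd.DataFrame(doses, index=lines, columns=[r[0] for r in rows]),
        family=pd.Series([f"F{k}" for k in fam_codes], index=lines),
        gmap=gmap,
    )
    y = pd.Series(rng.normal(size=n_lines), index=lines)
    return dosage, y, doses, fam_codes, gmap


class TestEncodeDosage:
    def test_coding_table(self, small_genos):
        dos = encode_dosage(small_genos)
        calls = small_genos.calls.to_numpy(dtype=object)
        dose = dos.dose.to_numpy()
        assert np.all(dose[calls == "B"] == 0.0)
        assert np.all(dose[calls == "H"] == 0.5)
        assert np.all(dose[calls == "D"] == 1.0)

    def test_family_mean_imputation(self):
        gmap = GeneticMap(pd.DataFrame(
            {"marker": ["m"], "chrom": [1], "pos_cm": [0.0]}
        ))
        lines = pd.Index(["a", "b", "c", "d"], name="line")
        genos = NILGenotypes(
            calls=pd.DataFrame({"m": ["B", "B", "D", np.nan]}, index=lines),
            family=pd.Series(["f"] * 4, index=lines),
            gmap=gmap,
        )
        dos = encode_dosage(genos)
        assert dos.dose.loc["d", "m"] == pytest.approx(1 / 3)
        assert encode_dosage(genos, impute="zero").dose.loc["d", "m"] == 0.0


class TestOracleEquivalence:
    """Engine results must match dense normal-equation computations."""

    @pytest.mark.parametrize("seed", range(6))
    def test_nested_pvalue_matches_bruteforce(self, seed):
        dosage, y, doses, fam_codes, _ = random_instance(seed)
        markers = dosage.markers
        for j, (base_idx, marker_idx) in enumerate(
            [([], 0), ([], 5), ([2], 7), ([1, 8], 4)]
        ):
            got = nested_marker_pvalue(
                y, dosage, markers[marker_idx], [markers[i] for i in base_idx]
            )
            want = oracles.nested_pvalue_bruteforce(
                y.to_numpy(), doses, fam_codes, base_idx, marker_idx
            )
            assert got == pytest.approx(want, rel=1e-8), (seed, j)

    @pytest.mark.parametrize("seed", range(6))
    def test_final_model_matches_ols(self, seed):
        dosage, y, doses, _, _ = random_instance(seed, n_lines=50)
        markers = [dosage.markers[i] for i in (1, 6)]
        model = fit_final_model(y, dosage, markers)
        # oracle design mirroring the package's column layout (families in
        # order of appearance); numerics are independent normal equations
        codes = pd.factorize(dosage.family)[0]
        X = [np.ones(len(y))]
        for k in range(1, codes.max() + 1):
            X.append((codes == k).astype(float))
        for i in (1, 6):
            Z = oracles.nested_columns(doses[:, i], codes)
            X.extend(Z.T)
        X = np.column_stack(X)
        beta, se, t, p, rss, r2 = oracles.ols_fit(X, y.to_numpy())
        assert np.allclose(model.coef["estimate"], beta, rtol=1e-8)
        assert np.allclose(model.coef["se"], se, rtol=1e-8)
        assert np.allclose(model.coef["p"], p, rtol=1e-7, atol=1e-300)
        assert model.rss == pytest.approx(rss, rel=1e-10)
        assert model.r2 == pytest.approx(r2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_forward_path_matches_exhaustive_scan(self, seed):
        dosage, _, doses, fam_codes, gmap = random_instance(seed, n_lines=60,
                                                            n_markers=18)
        rng = np.random.default_rng(seed + 100)
        # plant two effects so the path is non-trivial
        y_arr = (
            1.5 * doses[:, 3] * (fam_codes == 0)
            + 1.0 * doses[:, 10]
            + rng.normal(scale=0.7, size=len(fam_codes))
        )
        y = pd.Series(y_arr, index=dosage.lines)
        model = forward_select(y, dosage, threshold=0.05, max_qtl=6)
        chroms = gmap.table["chrom"].to_numpy()
        pos = gmap.table["pos_cm"].to_numpy()
        want_idx = oracles.forward_path_bruteforce(
            y_arr, doses, fam_codes, chroms, pos, threshold=0.05, max_qtl=6
        )
        assert model.markers == [dosage.markers[i] for i in want_idx]

    @pytest.mark.parametrize("seed", range(4))
    def test_lod_matches_bruteforce(self, seed):
        dosage, y, doses, fam_codes, _ = random_instance(seed, n_lines=50)
        markers = [dosage.markers[1], dosage.markers[8]]
        model = fit_final_model(y, dosage, markers)
        prof = lod_profile(y, dosage, model, markers[0])
        chrom = prof.chrom
        for _, row in prof.table.iterrows():
            j = dosage.markers.index(row["marker"])
            want = oracles.lod_bruteforce(y.to_numpy(), doses, fam_codes, [8], j)
            assert row["lod"] == pytest.approx(want, rel=1e-8, abs=1e-10)

    def test_genome_scan_matches_per_marker_pvalues(self, seed=0):
        dosage, y, doses, fam_codes, _ = random_instance(seed)
        scan = genome_scan_pvalues(y, dosage)
        for j, m in enumerate(dosage.markers):
            want = oracles.nested_pvalue_bruteforce(
                y.to_numpy(), doses, fam_codes, [], j
            )
            assert scan[m] == pytest.approx(want, rel=1e-8)


class TestNullBehaviour:
    def test_null_pvalues_uniform(self):
        """Under no association the nested-term p-value is Uniform(0,1)."""
        dosage, _, _, _, _ = random_instance(1, n_lines=80, n_markers=3)
        eng = GenomeScanEngine(dosage)
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(80, 1000))
        Yr = Y - eng.QF @ (eng.QF.T @ Y)
        pvals = eng.scan_columns(Yr)[0]  # first marker, 1000 null replicates
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_signal_p_is_zero(self):
        dosage, _, doses, fam_codes, _ = random_instance(3, n_lines=60)
        y = pd.Series(5.0 * doses[:, 2] * (fam_codes == 0), index=dosage.lines)
        assert nested_marker_pvalue(y, dosage, dosage.markers[2]) < 1e-30

    def test_non_segregating_marker_returns_one(self):
        dosage, y, doses, fam_codes, gmap = random_instance(4)
        dosage.dose.iloc[:, 0] = 0.0
        assert nested_marker_pvalue(y, dosage, dosage.markers[0]) == 1.0


class TestPermutationThreshold:
    def test_deterministic_given_seed(self, small_genos):
        dos = encode_dosage(small_genos)
        plots = simulate_phenotypes(small_genos, [], EnvSpec(), seed=2, traits=["t"])
        y = compute_lsmeans(plots)["t"]
        t1 = permutation_threshold(y, dos, n_perm=120, gwer=0.05, seed=9)
        t2 = permutation_threshold(y, dos, n_perm=120, gwer=0.05, seed=9)
        t3 = permutation_threshold(y, dos, n_perm=120, gwer=0.05, seed=10)
        assert t1 == t2
        assert t1 != t3
        assert 0 < t1 < 1

    def test_quantile_property_on_null_data(self, small_genos):
        """~gwer of null datasets fall below their own permutation threshold."""
        dos = encode_dosage(small_genos)
        eng = GenomeScanEngine(dos)
        rng = np.random.default_rng(5)
        hits = 0
        n_data = 60
        for i in range(n_data):
            y = pd.Series(rng.normal(size=len(dos.lines)), index=dos.lines)
            thr = eng.threshold(y, n_perm=120, gwer=0.2, seed=int(rng.integers(2**31)))
            hits += eng.scan(y).min() < thr
        # binomial 99% interval around 0.2 at n=60
        assert 4 <= hits <= 22

    def test_gwer_validation(self, small_genos):
        dos = encode_dosage(small_genos)
        y = pd.Series(np.zeros(len(dos.lines)) + np.arange(len(dos.lines)),
                      index=dos.lines)
        with pytest.raises(ValueError):
            permutation_threshold(y, dos, n_perm=120, gwer=1.5)
        with pytest.raises(ValueError):
            permutation_threshold(y, dos, n_perm=50, gwer=0.05)


class TestForwardSelection:
    def test_no_qtl_at_strict_threshold(self):
        dosage, y, *_ = random_instance(6, n_lines=80)
        model = forward_select(y, dosage, threshold=1e-8)
        assert model.markers == []

    def test_r2_nondecreasing_and_rss_nonincreasing_along_path(self):
        dosage, _, doses, fam_codes, _ = random_instance(7, n_lines=80,
                                                         n_markers=15)
        rng = np.random.default_rng(7)
        y = pd.Series(
            doses[:, 2] + 0.8 * doses[:, 9] + rng.normal(scale=0.5, size=80),
            index=dosage.lines,
        )
        model = forward_select(y, dosage, threshold=0.2, max_qtl=6)
        assert len(model.markers) >= 2
        rss_prev, r2_prev = np.inf, -np.inf
        for k in range(len(model.markers) + 1):
            sub = fit_final_model(y, dosage, model.markers[:k])
            assert sub.rss <= rss_prev + 1e-9
            assert sub.r2 >= r2_prev - 1e-9
            rss_prev, r2_prev = sub.rss, sub.r2

    def test_exact_linear_signal_recovered_exactly(self):
        dosage, _, doses, fam_codes, _ = random_instance(8, n_lines=60)
        y = pd.Series(3.0 - 2.0 * doses[:, 5] * (fam_codes == 1),
                      index=dosage.lines)
        model = fit_final_model(y, dosage, [dosage.markers[5]])
        eff = model.marker_effects(dosage.markers[5])
        row = eff[eff["family"] == "F1"].iloc[0]
        assert row["estimate"] == pytest.approx(-2.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)


class TestSupportInterval:
    def test_direct_example(self):
        prof = LODProfile(
            trait=None, qtl_marker="m3", chrom=1,
            table=pd.DataFrame({
                "marker": [f"m{i}" for i in range(1, 6)],
                "pos_cm": [0.0, 10.0, 20.0, 30.0, 40.0],
                "lod": [2.0, 9.0, 10.0, 9.5, 3.0],
            }),
        )
        assert support_interval(prof, drop=1.0) == (10.0, 30.0)

    def test_flat_profile_spans_chromosome(self):
        prof = LODProfile(
            trait=None, qtl_marker="m1", chrom=1,
            table=pd.DataFrame({
                "marker": ["m1", "m2", "m3"],
                "pos_cm": [0.0, 25.0, 50.0],
                "lod": [4.0, 4.0, 4.0],
            }),
        )
        assert support_interval(prof, drop=1.0) == (0.0, 50.0)

    def test_interval_contains_peak(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lods = rng.uniform(0, 10, size=9)
            pos = np.sort(rng.uniform(0, 100, size=9))
            prof = LODProfile(
                trait=None, qtl_marker="x", chrom=1,
                table=pd.DataFrame({
                    "marker": [f"m{i}" for i in range(9)],
                    "pos_cm": pos, "lod": lods,
                }),
            )
            lo, hi = support_interval(prof)
            peak_pos = pos[int(np.argmax(lods))]
            assert lo <= peak_pos <= hi

    def test_peak_lod_dominates_profile(self, small_genos):
        dos = encode_dosage(small_genos)
        marker = dos.markers[2]
        qtl = [QTLSpec(marker, "t", {"famA": -2.0, "famB": -1.0, "famC": 1.0})]
        plots = simulate_phenotypes(
            small_genos, qtl, EnvSpec(sigma2_g=0.1, sigma2_ge=0.05, sigma2_e=0.2),
            seed=21, traits=["t"], intercepts={"t": 0.0},
        )
        y = compute_lsmeans(plots)["t"]
        model = fit_final_model(y, dos, [marker], trait="t")
        prof = lod_profile(y, dos, model, marker)
        fitted = prof.table.set_index("marker").loc[marker, "lod"]
        assert fitted >= 0
        assert prof.table["lod"].max() == prof.table.set_index("marker")["lod"].max()


class TestAllelicEffects:
    def test_family_without_introgression_dashed(self):
        dosage, y, doses, fam_codes, _ = random_instance(12, n_lines=60)
        m = dosage.markers[4]
        mask = (dosage.family == "F2").to_numpy()
        dosage.dose.loc[mask, m] = 0.0
        model = fit_final_model(y, dosage, [m])
        rep = allelic_effect_table(model, dosage)
        assert rep.stars.loc[m, "F2"] == "-"
        assert np.isnan(rep.effects.loc[m, "F2"])

    def test_single_planted_effect_starred_in_right_family(self, small_genos):
        dos = encode_dosage(small_genos)
        m = dos.markers[5]
        qtl = [QTLSpec(m, "t", {"famB": 2.5})]
        plots = simulate_phenotypes(
            small_genos, qtl, EnvSpec(sigma2_g=0.05, sigma2_ge=0.02, sigma2_e=0.1),
            seed=31, traits=["t"], intercepts={"t": 0.0},
        )
        y = compute_lsmeans(plots)["t"]
        model = fit_final_model(y, dos, [m], trait="t")
        rep = allelic_effect_table(model, dos)
        assert rep.stars.loc[m, "famB"] in ("*", "**")
        assert rep.effects.loc[m, "famB"] > 0  # positive allele raises trait
        assert rep.n_significant_positive >= 1

    def test_sign_convention_negative_lowers_trait(self, small_genos):
        dos = encode_dosage(small_genos)
        m = dos.markers[1]
        plots = simulate_phenotypes(
            small_genos, [QTLSpec(m, "t", {"famA": -2.56})],
            EnvSpec(sigma2_g=0.02, sigma2_ge=0.01, sigma2_e=0.05),
            seed=41, traits=["t"], intercepts={"t": 70.0},
        )
        y = compute_lsmeans(plots)["t"]
        model = fit_final_model(y, dos, [m], trait="t")
        row = model.marker_effects(m)
        est = row[row["family"] == "famA"]["estimate"].iloc[0]
        assert est < 0
        assert est == pytest.approx(-2.56, abs=0.5)


class TestMapperEstimator:
    def test_sklearn_protocol(self):
        mapper = JointLinkageMapper(n_perm=150, gwer=0.1, seed=3)
        params = mapper.get_params()
        assert params["n_perm"] == 150
        mapper.set_params(gwer=0.05)
        assert mapper.gwer == 0.05
        with pytest.raises(ValueError):
            mapper.set_params(bogus=1)

    def test_sklearn_clone_compatible(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.base import clone

        mapper = JointLinkageMapper(n_perm=111, seed=7)
        cloned = clone(mapper)
        assert cloned.get_params() == mapper.get_params()

    def test_fit_predict_roundtrip(self, small_genos):
        dos = encode_dosage(small_genos)
        m = dos.markers[3]
        plots = simulate_phenotypes(
            small_genos, [QTLSpec(m, "t", {"famA": -3.0, "famB": -2.0, "famC": -2.5})],
            EnvSpec(sigma2_g=0.05, sigma2_ge=0.02, sigma2_e=0.1),
            seed=13, traits=["t"], intercepts={"t": 10.0},
        )
        y = compute_lsmeans(plots)["t"]
        mapper = JointLinkageMapper(threshold=1e-4, seed=1).fit(dos, y, trait="t")
        assert mapper.threshold_ == 1e-4
        pred = mapper.predict()
        assert pred.index.equals(dos.lines)
        if mapper.selected_markers_:
            assert np.corrcoef(pred, y.reindex(pred.index))[0, 1] > 0.5
            for mk, (lo, hi) in mapper.intervals_.items():
                chrom, pos = dos.gmap.marker_info(mk)
                assert lo <= pos <= hi
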