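"""QC-object construction: noob, control summaries, quantiles, flags,
sex prediction, SNP concordance and the privacy audit."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from methylfn.io import CONTROL_TYPES, RawSample
from methylfn.qc import (
    PrivacyError,
    QCObject,
    QCThresholds,
    SUBSET_KEYS,
    audit_privacy,
    bead_flags,
    build_control_matrix,
    build_qc_object,
    compute_quantiles,
    detection_pvalues,
    flag_outliers,
    noob_correct,
    normexp_signal,
    predict_sex,
    sample_qc,
    snp_concordance,
    summarize_controls,
)
from methylfn.synthetic import SimulationParams, make_manifest, simulate_dataset

from conftest import toy_manifest


# ---------------------------------------------------------------------------
# noob
# ---------------------------------------------------------------------------


class TestNormexp:
    @pytest.mark.parametrize("x,mu,sigma,theta", [
        (100.0, 50.0, 10.0, 200.0),
        (500.0, 100.0, 30.0, 1000.0),
        (60.0, 80.0, 25.0, 150.0),   # signal below background mean
        (3000.0, 100.0, 15.0, 2500.0),
        (150.0, 100.0, 5.0, 50.0),
    ])
    def test_matches_quadrature_oracle(self, x, mu, sigma, theta):
        """Posterior mean of the exponential signal equals direct numerical
        integration of the normal-exponential conditional expectation."""
        def dens(s):
            return np.exp(-s / theta) * stats.norm.pdf(x - s, mu, sigma)

        # density is concentrated where the normal factor is non-negligible
        upper = max(x - mu + 12 * sigma, 12 * sigma)
        peak = min(max(x - mu, 0.0), upper)
        num, _ = quad(lambda s: s * dens(s), 0, upper, points=[peak],
                      limit=400, epsabs=1e-300, epsrel=1e-12)
        den, _ = quad(dens, 0, upper, points=[peak],
                      limit=400, epsabs=1e-300, epsrel=1e-12)
        expected = num / den
        got = float(normexp_signal(np.array([x]), mu, sigma, theta)[0])
        assert abs(got - expected) / expected < 1e-6

    def test_sigma_zero_limit(self):
        """With vanishing background spread and x >> mu the corrected value
        tends to x - mu."""
        got = float(normexp_signal(np.array([1000.0]), 50.0, 1e-8, 500.0)[0])
        assert abs(got - 950.0) / 950.0 < 1e-3

    def test_strictly_positive(self):
        x = np.array([1.0, 10.0, 50.0, 100.0])
        out = normexp_signal(x, 200.0, 30.0, 100.0)
        assert (out > 0).all()


class TestNoobCorrect:
    def test_outputs_positive_and_channels_equalized(self, small_dataset,
                                                     small_manifest):
        dataset, _ = small_dataset
        s = dataset.samples[0]
        corrected = noob_correct(s, small_manifest)
        assert (corrected.meth > 0).all()
        assert (corrected.unmeth > 0).all()
        # the dye step equalizes the normalization-control means of the two
        # channels at their geometric mean
        man = small_manifest
        grn = corrected.control_intensities.loc[
            man.control_probes_of_type("norm.C").union(
                man.control_probes_of_type("norm.G"))].mean()
        red = corrected.control_intensities.loc[
            man.control_probes_of_type("norm.A").union(
                man.control_probes_of_type("norm.T"))].mean()
        assert abs(grn - red) / red < 1e-9
        # background-family controls collapse towards the normexp floor
        neg_raw = s.control_intensities.loc[
            man.control_probes_of_type("negative.grn")].mean()
        neg_cor = corrected.control_intensities.loc[
            man.control_probes_of_type("negative.grn")].mean()
        assert neg_cor < neg_raw / 2

    def test_symmetric_channels_leave_dye_scale_unity(self, small_manifest):
        """If both channels' normalization controls sit at the same level,
        the dye step must not rescale: corrected values depend only on the
        background correction."""
        dataset, _ = simulate_dataset(
            small_manifest,
            SimulationParams(n_samples=4, n_cpg_probes=480, n_snp_probes=10,
                             n_control_per_type=5, k_true=0, noise_sd=0.0,
                             slide_effect_sd=0, plate_effect_sd=0, seed=11))
        s = dataset.samples[0]
        # force exactly symmetric normalization controls
        ctrl = s.control_intensities.copy()
        man = small_manifest
        for ct in ("norm.A", "norm.T", "norm.C", "norm.G"):
            ctrl.loc[man.control_probes_of_type(ct)] = 5000.0
        import dataclasses
        s_sym = dataclasses.replace(s, control_intensities=ctrl)
        corrected = noob_correct(s_sym, man)
        # dye scale 1 on both channels: Type II meth (grn) and unmeth (red)
        # receive identical treatment; re-running with channels swapped via
        # the scale factor would otherwise change values
        norm_grn = corrected.control_intensities.loc[
            man.control_probes_of_type("norm.C")].mean()
        norm_red = corrected.control_intensities.loc[
            man.control_probes_of_type("norm.A")].mean()
        assert abs(norm_grn - norm_red) / norm_red < 1e-9

    def test_missing_oob_is_error(self, small_dataset, small_manifest):
        import dataclasses
        dataset, _ = small_dataset
        s = dataclasses.replace(dataset.samples[0],
                                oob=pd.DataFrame(columns=["meth", "unmeth"]))
        with pytest.raises(ValueError, match="out-of-band"):
            noob_correct(s, small_manifest)


# ---------------------------------------------------------------------------
# control summaries and quantiles
# ---------------------------------------------------------------------------


class TestSummarizeControls:
    def test_length_42(self, small_dataset, small_manifest):
        dataset, _ = small_dataset
        out = summarize_controls(dataset.samples[0], small_manifest)
        assert len(out) == 42
        assert list(out.index) == list(CONTROL_TYPES)

    def test_constant_and_hand_mean(self, small_dataset, small_manifest):
        import dataclasses
        dataset, _ = small_dataset
        s = dataset.samples[0]
        ctrl = pd.Series(77.0, index=s.control_intensities.index)
        out = summarize_controls(dataclasses.replace(s, control_intensities=ctrl),
                                 small_manifest)
        assert (out == 77.0).all()
        # 2-probe toy mean: set one type's probes to 100 and 300
        ids = small_manifest.control_probes_of_type("extension.A")[:2]
        ctrl2 = ctrl.copy()
        ctrl2.loc[ids] = [100.0, 300.0]
        ctrl2 = ctrl2.drop(small_manifest.control_probes_of_type("extension.A")[2:])
        out2 = summarize_controls(dataclasses.replace(s, control_intensities=ctrl2),
                                  small_manifest)
        assert out2["extension.A"] == 200.0

    def test_missing_type_listed(self, small_dataset, small_manifest):
        import dataclasses
        dataset, _ = small_dataset
        s = dataset.samples[0]
        keep = s.control_intensities.drop(
            small_manifest.control_probes_of_type("restoration"))
        with pytest.raises(ValueError, match="restoration"):
            summarize_controls(dataclasses.replace(s, control_intensities=keep),
                               small_manifest)


class TestComputeQuantiles:
    def test_all_18_subsets_present_and_monotone(self, small_dataset,
                                                 small_manifest):
        dataset, _ = small_dataset
        q = compute_quantiles(dataset.samples[0], small_manifest, n_q=25)
        assert set(q.keys()) == set(SUBSET_KEYS)
        for vec in q.values():
            if len(vec):
                assert (np.diff(vec) >= 0).all()

    def test_constant_subset(self, small_dataset, small_manifest):
        import dataclasses
        dataset, _ = small_dataset
        s = dataset.samples[0]
        meth = pd.Series(500.0, index=s.meth.index)
        q = compute_quantiles(dataclasses.replace(s, meth=meth),
                              small_manifest, n_q=11)
        assert (q["II.meth.autosomal"] == 500.0).all()

    def test_brute_force_quantile_oracle(self):
        """Quantiles of 1..100 at five probabilities match explicit
        sort-and-interpolate arithmetic."""
        rows = [(f"p{i}", "II", "both", "cpg", None, "1") for i in range(100)]
        manifest = toy_manifest(rows)
        ids = manifest.assay_probe_ids
        sample = RawSample(
            sample_id="s", meth=pd.Series(np.arange(1.0, 101.0), index=ids),
            unmeth=pd.Series(1.0, index=ids),
            oob=pd.DataFrame(columns=["meth", "unmeth"], dtype=float),
            control_intensities=pd.Series(dtype=float),
            bead_counts=pd.Series(10, index=ids))
        q = compute_quantiles(sample, manifest, n_q=5)["II.meth.autosomal"]

        def brute(values, p):  # independent linear-interpolation oracle
            v = sorted(values)
            h = (len(v) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(v) - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        expected = [brute(np.arange(1.0, 101.0), p)
                    for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert np.allclose(q, expected)

    def test_empty_subset_explicit_marker(self):
        manifest = toy_manifest([("p0", "II", "both", "cpg", None, "1")])
        ids = manifest.assay_probe_ids
        sample = RawSample(
            sample_id="s", meth=pd.Series(10.0, index=ids),
            unmeth=pd.Series(10.0, index=ids),
            oob=pd.DataFrame(columns=["meth", "unmeth"], dtype=float),
            control_intensities=pd.Series(dtype=float),
            bead_counts=pd.Series(10, index=ids))
        q = compute_quantiles(sample, manifest, n_q=5)
        assert "II.meth.Y" in q and len(q["II.meth.Y"]) == 0


# ---------------------------------------------------------------------------
# detection p-values, beads, sex
# ---------------------------------------------------------------------------


def _detection_fixture(signal_total):
    rows = [("cg1", "II", "both", "cpg", None, "1")]
    for i, ct in enumerate(("negative.grn", "negative.red")):
        ch = "grn" if "grn" in ct else "red"
        for r in range(3):
            rows.append((f"c{ct}{r}", "I", ch, "control", ct, "1"))
    # a normalization complement so the manifest stays generic
    manifest = toy_manifest(rows)
    neg = [40.0, 50.0, 60.0]  # mean 50, sd 10 per channel
    ctrl = pd.Series(neg + neg,
                     index=[f"c{ct}{r}" for ct in ("negative.grn", "negative.red")
                            for r in range(3)])
    ids = manifest.assay_probe_ids
    sample = RawSample(
        sample_id="s", meth=pd.Series(signal_total / 2.0, index=ids),
        unmeth=pd.Series(signal_total / 2.0, index=ids),
        oob=pd.DataFrame(columns=["meth", "unmeth"], dtype=float),
        control_intensities=ctrl, bead_counts=pd.Series(10, index=ids))
    return sample, manifest


class TestDetectionPvalues:
    def test_signal_at_background_mean_gives_half(self):
        sample, manifest = _detection_fixture(signal_total=100.0)
        p = detection_pvalues(sample, manifest)
        assert abs(p.iloc[0] - 0.5) < 1e-12

    def test_ten_sd_signal_is_tiny(self):
        # combined background sd = sqrt(2)*10
        sample, manifest = _detection_fixture(100.0 + 10 * np.sqrt(200.0))
        p = detection_pvalues(sample, manifest)
        assert p.iloc[0] < 1e-9

    def test_normal_tail_oracle(self):
        sd = float(np.sqrt(200.0))
        sample, manifest = _detection_fixture(100.0 + 1.96 * sd)
        p = detection_pvalues(sample, manifest)
        assert abs(p.iloc[0] - (1.0 - stats.norm.cdf(1.96))) < 1e-3

    def test_too_few_negative_controls(self):
        sample, manifest = _detection_fixture(100.0)
        short = sample.control_intensities.drop("cnegative.grn0")
        import dataclasses
        with pytest.raises(ValueError, match="negative controls"):
            detection_pvalues(dataclasses.replace(sample, control_intensities=short),
                              manifest)


class TestBeadFlags:
    def test_enumeration(self):
        s = RawSample("s", pd.Series(dtype=float), pd.Series(dtype=float),
                      pd.DataFrame(columns=["meth", "unmeth"]),
                      pd.Series(dtype=float),
                      bead_counts=pd.Series({"a": 2, "b": 3, "c": 5}))
        assert bead_flags(s, threshold=3) == {"a"}
        assert bead_flags(s, threshold=0) == set()
        assert bead_flags(s, threshold=2) == set()


class TestPredictSex:
    def test_cohort_recovery(self):
        params = SimulationParams(n_samples=100, n_cpg_probes=480,
                                  n_control_per_type=5, seed=21)
        manifest = make_manifest("450k-like", params)
        dataset, truth = simulate_dataset(manifest, params)
        predicted = {s.sample_id: build_qc_object(s, manifest, n_q=20).predicted_sex
                     for s in dataset.samples}
        assert all(predicted[sid] == truth.true_sex[sid]
                   for sid in truth.true_sex.index)

    def test_missing_sex_chromosomes_undetermined(self):
        q = {k: np.array([100.0, 200.0]) for k in SUBSET_KEYS
             if k.endswith("autosomal")}
        q.update({k: np.array([]) for k in SUBSET_KEYS
                  if not k.endswith("autosomal")})
        assert predict_sex(q) == "U"


# ---------------------------------------------------------------------------
# cohort QC
# ---------------------------------------------------------------------------


class TestSampleQC:
    def test_planted_meth_scale_outlier_flagged(self, small_dataset,
                                                small_manifest):
        import dataclasses
        dataset, _ = small_dataset
        samples = list(dataset.samples)
        bad = dataclasses.replace(samples[3], meth=samples[3].meth * 10.0)
        samples[3] = bad
        qcs = [build_qc_object(s, small_manifest, n_q=30) for s in samples]
        report = sample_qc(qcs, n_probes=len(small_manifest.assay_probe_ids))
        flags = report.sample_table["meth_unmeth_ratio"]
        assert flags[bad.sample_id]
        assert flags.drop(bad.sample_id).sum() == 0

    def test_declared_sex_mismatch_flagged_exactly_once(self, small_dataset,
                                                        small_manifest):
        dataset, truth = small_dataset
        qcs = [build_qc_object(s, small_manifest, n_q=30) for s in dataset.samples]
        victim = qcs[2].sample_id
        declared = {sid: sex for sid, sex in truth.true_sex.items()}
        declared[victim] = "M" if declared[victim] == "F" else "F"
        report = sample_qc(qcs, n_probes=len(small_manifest.assay_probe_ids),
                           declared_sex=declared)
        flags = report.sample_table["sex_mismatch"]
        assert flags[victim] and flags.sum() == 1

    def test_null_outlier_rate_matches_gaussian_tail(self):
        """The 3-SD rule flags about 0.27% of clean Gaussian cohorts."""
        rng = np.random.default_rng(0)
        flagged, total = 0, 0
        for _ in range(20):
            vals = pd.Series(rng.standard_normal(1000))
            flagged += int(flag_outliers(vals, 3.0).sum())
            total += 1000
        rate = flagged / total
        assert 0.0005 < rate < 0.006  # binomial tolerance around 0.0027

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="max_undetected_frac"):
            QCThresholds(max_undetected_frac=1.5)


# ---------------------------------------------------------------------------
# SNP concordance
# ---------------------------------------------------------------------------


class TestSnpConcordance:
    def test_noiseless_encoding_perfect(self):
        geno = pd.DataFrame([[0, 1, 2, 1], [2, 2, 0, 0]],
                            index=["a", "b"], columns=list("wxyz"))
        betas = geno / 2.0
        conc = snp_concordance(betas, geno)
        assert conc.loc["a", "a"] == 1.0 and conc.loc["b", "b"] == 1.0
        assert conc.loc["a", "b"] < 1.0

    def test_single_shared_snp_mismatch(self):
        geno = pd.DataFrame([[2]], index=["a"], columns=["s1"])
        betas = pd.DataFrame([[0.0]], index=["a"], columns=["s1"])
        assert snp_concordance(betas, geno).loc["a", "a"] == 0.0

    def test_random_pair_matches_enumeration_oracle(self):
        """Concordance of unrelated samples equals the sum of squared
        genotype frequencies under Hardy-Weinberg."""
        rng = np.random.default_rng(5)
        maf = 0.3
        freqs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        expected = float((freqs**2).sum())  # enumeration over genotype pairs
        n_snp = 4000
        g1 = rng.choice([0, 1, 2], size=n_snp, p=freqs)
        g2 = rng.choice([0, 1, 2], size=n_snp, p=freqs)
        cols = [f"s{i}" for i in range(n_snp)]
        betas = pd.DataFrame([g1 / 2.0], index=["a"], columns=cols)
        geno = pd.DataFrame([g2], index=["b"], columns=cols)
        got = snp_concordance(betas, geno).loc["a", "b"]
        assert abs(got - expected) < 3 * np.sqrt(expected * (1 - expected) / n_snp)

    def test_no_shared_snps(self):
        with pytest.raises(ValueError, match="no shared"):
            snp_concordance(pd.DataFrame([[0.5]], columns=["x"]),
                            pd.DataFrame([[1]], columns=["y"]))


# ---------------------------------------------------------------------------
# privacy audit and serialization
# ---------------------------------------------------------------------------


class TestPrivacy:
    def test_serialized_qc_object_passes_audit(self, small_qcs):
        payload = json.loads(small_qcs[0].to_json())
        audit_privacy(payload)  # must not raise

    def test_injected_beta_field_fails_audit(self, small_qcs):
        payload = small_qcs[0].to_dict()
        payload["betas"] = [0.5] * 1000
        with pytest.raises(PrivacyError, match="betas"):
            audit_privacy(payload)

    def test_probe_length_vector_fails_audit(self, small_qcs):
        payload = small_qcs[0].to_dict()
        payload["quantiles"]["II.meth.autosomal"] = [0.5] * 9999
        with pytest.raises(PrivacyError, match="length"):
            audit_privacy(payload)

    def test_round_trip_preserves_fields(self, small_qcs):
        qc = small_qcs[0]
        back = QCObject.from_dict(json.loads(qc.to_json()))
        assert back.sample_id == qc.sample_id
        assert np.allclose(back.control_summary, qc.control_summary)
        for key in SUBSET_KEYS:
            assert np.allclose(back.quantiles[key], qc.quantiles[key])
        assert back.batch == qc.batch


class TestControlMatrix:
    def test_shape_and_order_independence(self, small_qcs):
        cm = build_control_matrix(small_qcs)
        assert cm.shape == (42, len(small_qcs))
        cm_rev = build_control_matrix(list(reversed(small_qcs)))
        assert cm_rev[cm.columns].equals(cm)

    def test_duplicate_sample_rejected(self, small_qcs):
        with pytest.raises(ValueError, match="duplicate"):
            build_control_matrix([small_qcs[0], small_qcs[0]])
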