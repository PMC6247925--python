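"""Per-sample QC objects: noob correction, control summaries, quantiles, flags.

The QC object is the package's central summary: for each sample it holds the
42-entry control-probe summary vector, empirical intensity quantiles for the
18 (probe class x signal x chromosome group) subsets, detection/bead failure
sets, predicted sex and batch labels.  It deliberately contains **no
probe-level biological measurements** — the privacy contract that makes
multi-site normalization non-disclosive — and :func:`audit_privacy` enforces
that on every serialized object.

noob background correction models each observed intensity as signal plus
background, with exponential signal (mean ``theta``) and normal background
(``mu``, ``sigma`` estimated per channel from out-of-band intensities); the
corrected intensity is the posterior mean of the signal.  Dye bias is then
removed by scaling each channel so its mean normalization-control intensity
equals the geometric mean of the two channels' levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    CONTROL_TYPES,
    Manifest,
    NEGATIVE_CONTROL_TYPES,
    NORMALIZATION_CONTROL_TYPES,
    RawSample,
)

__all__ = [
    "SUBSET_KEYS",
    "QCObject",
    "QCThresholds",
    "SampleQCReport",
    "PrivacyError",
    "noob_correct",
    "normexp_signal",
    "summarize_controls",
    "compute_quantiles",
    "detection_pvalues",
    "bead_flags",
    "predict_sex",
    "build_qc_object",
    "build_control_matrix",
    "sample_qc",
    "flag_outliers",
    "snp_concordance",
    "audit_privacy",
]

_PROBE_CLASSES = ("I-grn", "I-red", "II")
_SIGNALS = ("meth", "unmeth")
_CHROM_GROUPS = ("autosomal", "X", "Y")

#: The 18 quantile subsets: probe class x signal x chromosome group.  Sex
#: chromosomes are kept separate so sex differences are not normalized away.
SUBSET_KEYS: tuple[str, ...] = tuple(
    f"{c}.{s}.{g}" for c in _PROBE_CLASSES for s in _SIGNALS for g in _CHROM_GROUPS
)

_DEFAULT_NQ = 500


# ---------------------------------------------------------------------------
# noob: normal-exponential background + dye-bias correction
# ---------------------------------------------------------------------------


def normexp_signal(x: np.ndarray, mu: float, sigma: float, theta: float) -> np.ndarray:
    """Posterior mean of the signal under the normal-exponential model.

    Observed ``x = s + b`` with ``s ~ Exp(mean=theta)`` and
    ``b ~ N(mu, sigma^2)``.  Returns ``E[s | x]``, which is strictly
    positive.  As ``sigma -> 0`` with ``x >> mu`` this tends to ``x - mu``.
    """
    x = np.asarray(x, dtype=float)
    sigma = max(float(sigma), 1e-12)
    theta = max(float(theta), 1e-12)
    mu_sf = x - mu - sigma**2 / theta
    z = mu_sf / sigma
    # log(phi(z)) - log(Phi(z)) is stable for very negative z
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    signal = mu_sf + sigma * np.exp(log_ratio)
    return np.maximum(signal, 1e-6)


def _channel_of_assay(manifest: Manifest) -> pd.DataFrame:
    """Per assay probe: which channel carries meth and unmeth signal."""
    t = manifest.table
    assay = t[t["target"].isin(["cpg", "snp"])]
    # Type I: both signals in the probe's channel.  Type II: meth is read in
    # green, unmeth in red.
    meth_ch = np.where(assay["probe_type"] == "I", assay["channel"], "grn")
    unmeth_ch = np.where(assay["probe_type"] == "I", assay["channel"], "red")
    return pd.DataFrame({"meth": meth_ch, "unmeth": unmeth_ch},
                        index=pd.Index(assay["probe_id"]))


def noob_correct(sample: RawSample, manifest: Manifest) -> RawSample:
    """Background- and dye-bias-correct one sample (returns a new sample).

    Background parameters come from the out-of-band intensities: green
    background from the oob of Type I red probes (measured in green), red
    background from the oob of Type I grn probes.  The exponential signal
    mean is estimated per channel by method of moments on the foreground.
    A non-positive variance estimate is floored at 1 (documented fallback);
    the signal mean is floored at 1.
    """
    if sample.oob is None or len(sample.oob) == 0:
        raise ValueError(
            f"sample {sample.sample_id}: no out-of-band intensities; "
            "noob background estimation needs Type I opposite-channel signal"
        )
    t1_grn = manifest.type1_probe_ids("grn")
    t1_red = manifest.type1_probe_ids("red")
    oob_grn_vals = np.concatenate([
        sample.oob.loc[sample.oob.index.intersection(t1_red), "meth"].to_numpy(),
        sample.oob.loc[sample.oob.index.intersection(t1_red), "unmeth"].to_numpy(),
    ])
    oob_red_vals = np.concatenate([
        sample.oob.loc[sample.oob.index.intersection(t1_grn), "meth"].to_numpy(),
        sample.oob.loc[sample.oob.index.intersection(t1_grn), "unmeth"].to_numpy(),
    ])
    if len(oob_grn_vals) == 0 or len(oob_red_vals) == 0:
        raise ValueError(
            f"sample {sample.sample_id}: out-of-band intensities must cover both channels"
        )

    params = {}
    channels = _channel_of_assay(manifest)
    channels = channels.reindex(sample.meth.index)
    for ch, vals in (("grn", oob_grn_vals), ("red", oob_red_vals)):
        mu = float(np.mean(vals))
        sigma = float(np.std(vals, ddof=1))
        if not np.isfinite(sigma) or sigma <= 0:
            sigma = 1.0  # degenerate background: fall back to unit spread
        fg = np.concatenate([
            sample.meth.to_numpy()[(channels["meth"] == ch).to_numpy()],
            sample.unmeth.to_numpy()[(channels["unmeth"] == ch).to_numpy()],
        ])
        theta = max(float(np.mean(fg)) - mu, 1.0)
        params[ch] = (mu, sigma, theta)

    def correct(values: np.ndarray, chans: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float)
        for ch in ("grn", "red"):
            m = chans == ch
            if m.any():
                out[m] = normexp_signal(out[m], *params[ch])
        return out

    meth = pd.Series(correct(sample.meth.to_numpy(), channels["meth"].to_numpy()),
                     index=sample.meth.index)
    unmeth = pd.Series(correct(sample.unmeth.to_numpy(), channels["unmeth"].to_numpy()),
                       index=sample.unmeth.index)

    # controls: background-correct channel-resolved controls, then compute
    # the dye-bias reference from the normalization-control families
    ctrl_tab = manifest.probes("control").set_index("probe_id")
    ctrl_ch = ctrl_tab["channel"].reindex(sample.control_intensities.index).to_numpy()
    ctrl_vals = correct(sample.control_intensities.to_numpy(), ctrl_ch)
    ctrl = pd.Series(ctrl_vals, index=sample.control_intensities.index)

    norm_means = {}
    for ch, types in NORMALIZATION_CONTROL_TYPES.items():
        ids = pd.Index([])
        for ct in types:
            ids = ids.union(manifest.control_probes_of_type(ct))
        vals = ctrl.reindex(ids.intersection(ctrl.index)).dropna()
        if len(vals) == 0:
            raise ValueError(f"no normalization controls for channel {ch}")
        norm_means[ch] = float(vals.mean())
    reference = float(np.sqrt(norm_means["grn"] * norm_means["red"]))
    scale = {ch: reference / norm_means[ch] for ch in ("grn", "red")}

    def rescale(values: pd.Series, chans: np.ndarray) -> pd.Series:
        out = values.to_numpy().copy()
        for ch in ("grn", "red"):
            m = chans == ch
            out[m] *= scale[ch]
        return pd.Series(out, index=values.index)

    meth = rescale(meth, channels["meth"].to_numpy())
    unmeth = rescale(unmeth, channels["unmeth"].to_numpy())
    ctrl = rescale(ctrl, ctrl_ch)

    return replace(sample, meth=meth, unmeth=unmeth, control_intensities=ctrl)


# ---------------------------------------------------------------------------
# Control summarization and quantiles
# ---------------------------------------------------------------------------


def summarize_controls(sample: RawSample, manifest: Manifest) -> pd.Series:
    """One summary value per control type: mean raw intensity over the
    type's probes.  Length is exactly 42; missing types are an error."""
    ctrl = manifest.probes("control")
    present = set(ctrl["control_type"])
    missing = [t for t in CONTROL_TYPES if t not in present]
    if missing:
        raise ValueError(f"manifest missing control types: {missing}")
    grouped = sample.control_intensities.groupby(
        ctrl.set_index("probe_id")["control_type"].reindex(sample.control_intensities.index)
    ).mean()
    out = grouped.reindex(list(CONTROL_TYPES))
    if out.isna().any():
        absent = list(out.index[out.isna()])
        raise ValueError(f"sample {sample.sample_id}: no intensities for control types {absent}")
    out.name = sample.sample_id
    return out


def _subset_masks(manifest: Manifest) -> dict[str, np.ndarray]:
    """Boolean masks over cpg probes for the 18 subsets (snp probes excluded
    from quantile subsets; they are carried through normalization raw)."""
    t = manifest.table
    cpg = t[t["target"] == "cpg"].reset_index(drop=True)
    cls = np.where(cpg["probe_type"] == "II", "II",
                   np.where(cpg["channel"] == "grn", "I-grn", "I-red"))
    chrom = cpg["chromosome"].to_numpy()
    group = np.where(chrom == "X", "X", np.where(chrom == "Y", "Y", "autosomal"))
    masks = {}
    for key in SUBSET_KEYS:
        c, _signal, g = key.split(".")
        masks[key] = (cls == c) & (group == g)
    return masks, pd.Index(cpg["probe_id"])


def compute_quantiles(sample: RawSample, manifest: Manifest,
                      n_q: int = _DEFAULT_NQ) -> dict[str, np.ndarray]:
    """Empirical quantiles of (noob-corrected) intensities per subset.

    For each of the 18 subset keys, the quantiles at ``n_q`` evenly spaced
    probabilities in [0, 1].  An empty subset yields an explicit empty
    vector (the key is always present).
    """
    if n_q < 2:
        raise ValueError("n_q must be >= 2")
    probs = np.linspace(0.0, 1.0, n_q)
    masks, cpg_ids = _subset_masks(manifest)
    out: dict[str, np.ndarray] = {}
    for key in SUBSET_KEYS:
        signal = key.split(".")[1]
        values = (sample.meth if signal == "meth" else sample.unmeth)
        x = values.reindex(cpg_ids).to_numpy()[masks[key]]
        if x.size == 0:
            out[key] = np.array([])  # explicit empty-subset marker
        else:
            out[key] = np.quantile(x, probs)
    return out


# ---------------------------------------------------------------------------
# Detection p-values, bead flags, sex
# ---------------------------------------------------------------------------


def detection_pvalues(sample: RawSample, manifest: Manifest) -> pd.Series:
    """One-sided p-value that a probe's total signal exceeds background.

    Background is the per-channel negative-control distribution (normal
    approximation); for Type I probes both alleles are read in one channel
    (background mean doubles), for Type II the channels are summed.
    """
    bg = {}
    for ch, ct in NEGATIVE_CONTROL_TYPES.items():
        ids = manifest.control_probes_of_type(ct)
        vals = sample.control_intensities.reindex(ids).dropna()
        if len(vals) < 3:
            raise ValueError(f"fewer than 3 negative controls in channel {ch}")
        bg[ch] = (float(vals.mean()), float(vals.std(ddof=1)))

    t = manifest.table
    assay = t[t["target"].isin(["cpg", "snp"])]
    total = (sample.meth + sample.unmeth).reindex(assay["probe_id"]).to_numpy()
    is_t1 = (assay["probe_type"] == "I").to_numpy()
    chan = assay["channel"].to_numpy()
    mu = np.empty(len(assay))
    sd = np.empty(len(assay))
    for ch in ("grn", "red"):
        m = is_t1 & (chan == ch)
        mu[m] = 2.0 * bg[ch][0]
        sd[m] = np.sqrt(2.0) * bg[ch][1]
    m2 = ~is_t1
    mu[m2] = bg["grn"][0] + bg["red"][0]
    sd[m2] = np.sqrt(bg["grn"][1] ** 2 + bg["red"][1] ** 2)
    p = stats.norm.sf(total, loc=mu, scale=sd)
    return pd.Series(p, index=pd.Index(assay["probe_id"]), name=sample.sample_id)


def bead_flags(sample: RawSample, threshold: int = 3) -> set[str]:
    """Probes with bead count strictly below ``threshold`` (default 3)."""
    if threshold <= 0:
        return set()
    return set(sample.bead_counts.index[sample.bead_counts < threshold])


_SEX_LOG2_CUTOFF = -2.0


def predict_sex(quantiles: Mapping[str, np.ndarray],
                cutoff: float = _SEX_LOG2_CUTOFF) -> str:
    """Classify sex from the chrY-vs-chrX median log2 intensity difference.

    Returns ``"M"``, ``"F"``, or ``"U"`` (undetermined) when sex-chromosome
    subsets are empty.
    """
    def pooled(group: str) -> np.ndarray:
        vecs = [np.asarray(quantiles.get(f"{c}.{s}.{group}", []))
                for c in _PROBE_CLASSES for s in _SIGNALS]
        vecs = [v for v in vecs if v.size]
        return np.concatenate(vecs) if vecs else np.array([])

    y, x = pooled("Y"), pooled("X")
    if y.size == 0 or x.size == 0:
        return "U"
    diff = float(np.median(np.log2(np.maximum(y, 1e-6)))
                 - np.median(np.log2(np.maximum(x, 1e-6))))
    return "M" if diff > cutoff else "F"


# ---------------------------------------------------------------------------
# QCObject
# ---------------------------------------------------------------------------

_QC_SCHEMA_FIELDS = {
    "sample_id", "control_summary", "quantiles", "detection_fail", "bead_fail",
    "predicted_sex", "qc_flags", "batch", "n_q",
}
_FLAG_NAMES = ("meth_unmeth_ratio", "dye_bias", "control_outlier", "sex_mismatch",
               "detection_fraction", "bead_fraction")


class PrivacyError(ValueError):
    """A serialized QC payload contains disallowed (probe-level) data."""


@dataclass
class QCObject:
    """Non-disclosive per-sample summary sufficient for joint normalization."""

    sample_id: str
    control_summary: pd.Series  # 42 entries, indexed by control type
    quantiles: dict[str, np.ndarray]  # 18 subset keys
    detection_fail: set[str] = field(default_factory=set)
    bead_fail: set[str] = field(default_factory=set)
    predicted_sex: str = "U"
    qc_flags: dict[str, bool] = field(default_factory=dict)
    batch: dict[str, str] = field(default_factory=dict)
    n_q: int = _DEFAULT_NQ

    def __post_init__(self) -> None:
        if len(self.control_summary) != 42:
            raise ValueError(
                f"control_summary must have exactly 42 entries, got {len(self.control_summary)}"
            )
        for key, vec in self.quantiles.items():
            v = np.asarray(vec)
            if v.size and np.any(np.diff(v) < -1e-9):
                raise ValueError(f"quantile vector {key} is not non-decreasing")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "control_summary": {k: float(v) for k, v in self.control_summary.items()},
            "quantiles": {k: [float(x) for x in np.asarray(v)]
                          for k, v in self.quantiles.items()},
            "detection_fail": sorted(self.detection_fail),
            "bead_fail": sorted(self.bead_fail),
            "predicted_sex": self.predicted_sex,
            "qc_flags": {k: bool(v) for k, v in self.qc_flags.items()},
            "batch": dict(self.batch),
            "n_q": self.n_q,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QCObject":
        audit_privacy(d)
        return cls(
            sample_id=d["sample_id"],
            control_summary=pd.Series(d["control_summary"]).reindex(list(CONTROL_TYPES)),
            quantiles={k: np.asarray(v, dtype=float) for k, v in d["quantiles"].items()},
            detection_fail=set(d.get("detection_fail", ())),
            bead_fail=set(d.get("bead_fail", ())),
            predicted_sex=d.get("predicted_sex", "U"),
            qc_flags=dict(d.get("qc_flags", {})),
            batch=dict(d.get("batch", {})),
            n_q=int(d.get("n_q", _DEFAULT_NQ)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def audit_privacy(payload: Mapping) -> None:
    """Schema audit: reject payloads carrying probe-level cpg measurements.

    Allowed fields are exactly the QC-object schema; any extra field (e.g.
    an injected ``betas`` matrix), a control summary of the wrong length, or
    a quantile vector longer than ``n_q`` fails the audit.
    """
    extra = set(payload.keys()) - _QC_SCHEMA_FIELDS
    if extra:
        raise PrivacyError(f"disallowed fields in QC payload: {sorted(extra)}")
    missing = {"sample_id", "control_summary", "quantiles"} - set(payload.keys())
    if missing:
        raise PrivacyError(f"QC payload missing required fields: {sorted(missing)}")
    if len(payload["control_summary"]) != 42:
        raise PrivacyError("control_summary must have exactly 42 entries")
    n_q = int(payload.get("n_q", _DEFAULT_NQ))
    quants = payload["quantiles"]
    unknown = set(quants.keys()) - set(SUBSET_KEYS)
    if unknown:
        raise PrivacyError(f"unknown quantile subsets: {sorted(unknown)}")
    for key, vec in quants.items():
        if len(vec) not in (0, n_q):
            raise PrivacyError(
                f"quantile vector {key} has length {len(vec)}; expected 0 or n_q={n_q} "
                "(probe-level vectors are not allowed)"
            )


def build_qc_object(sample: RawSample, manifest: Manifest, n_q: int = _DEFAULT_NQ,
                    detection_p: float = 0.01, bead_threshold: int = 3) -> QCObject:
    """Assemble the QC object for one sample.

    Control summaries and detection p-values use the raw intensities;
    quantiles are computed after noob correction (the inputs to functional
    normalization).
    """
    summary = summarize_controls(sample, manifest)
    det = detection_pvalues(sample, manifest)
    corrected = noob_correct(sample, manifest)
    quantiles = compute_quantiles(corrected, manifest, n_q=n_q)
    sex = predict_sex(quantiles)
    return QCObject(
        sample_id=sample.sample_id,
        control_summary=summary,
        quantiles=quantiles,
        detection_fail=set(det.index[det > detection_p]),
        bead_fail=bead_flags(sample, threshold=bead_threshold),
        predicted_sex=sex,
        qc_flags={name: False for name in _FLAG_NAMES},
        batch=dict(sample.batch),
        n_q=n_q,
    )


def build_control_matrix(qc_objects: Sequence[QCObject]) -> pd.DataFrame:
    """42 x n_samples control matrix: one row per control type, one column
    per sample.  Column order follows the input; assembly is otherwise
    order-independent."""
    cols = {}
    for qc in qc_objects:
        if qc.sample_id in cols:
            raise ValueError(f"duplicate sample id {qc.sample_id}")
        cols[qc.sample_id] = qc.control_summary.reindex(list(CONTROL_TYPES))
    return pd.DataFrame(cols, index=list(CONTROL_TYPES))


# ---------------------------------------------------------------------------
# Cohort-level QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Cohort QC thresholds (all configurable).

    ``outlier_sd`` is the z-score rule for ratio / dye-bias / control
    outliers; ``max_undetected_frac`` / ``max_bead_frac`` bound the fraction
    of failing probes a sample may carry; ``probe_fail_frac`` is the fraction
    of samples in which a probe may fail before it is excluded cohort-wide.
    """

    detection_p: float = 0.01
    bead_threshold: int = 3
    outlier_sd: float = 3.0
    max_undetected_frac: float = 0.1
    max_bead_frac: float = 0.1
    probe_fail_frac: float = 0.2

    def __post_init__(self) -> None:
        for name in ("detection_p", "max_undetected_frac", "max_bead_frac",
                     "probe_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


def flag_outliers(values: pd.Series, n_sd: float = 3.0) -> pd.Series:
    """Two-sided robust z-score outlier rule.

    Uses median and MAD (scaled by 1.4826 so the rule matches the Gaussian
    SD rule asymptotically); unlike mean/SD this is not masked by the
    outlier itself in small cohorts.
    """
    v = values.astype(float)
    med = v.median()
    mad = 1.4826 * (v - med).abs().median()
    if not np.isfinite(mad) or mad == 0:
        return pd.Series(False, index=v.index)
    z = (v - med) / mad
    return z.abs() > n_sd


@dataclass
class SampleQCReport:
    sample_table: pd.DataFrame  # per-sample statistics + boolean flags
    probe_exclusions: list[str]
    thresholds: QCThresholds

    @property
    def failed_samples(self) -> list[str]:
        hard = ["detection_fraction", "bead_fraction", "sex_mismatch"]
        t = self.sample_table
        return list(t.index[t[hard].any(axis=1)])


def sample_qc(qc_objects: Sequence[QCObject],
              thresholds: QCThresholds | None = None,
              n_probes: int | None = None,
              declared_sex: Mapping[str, str] | None = None) -> SampleQCReport:
    """Cohort QC: outlier flags per sample plus a probe exclusion list.

    Flags: meth/unmeth median-intensity ratio outliers, dye-bias (red/green
    normalization-control ratio) outliers, control-probe outliers (beyond
    ``outlier_sd`` SDs from the cohort mean for any control type), excess
    undetected-probe / low-bead fractions, and declared-vs-predicted sex
    mismatches.  Outlier flags are review flags; the hard failure criteria
    are the fraction thresholds and sex mismatch.
    """
    if len(qc_objects) < 2:
        raise ValueError("cohort QC needs at least 2 samples")
    thr = thresholds or QCThresholds()
    ids = [qc.sample_id for qc in qc_objects]

    def med_signal(qc: QCObject, signal: str) -> float:
        vecs = [np.asarray(qc.quantiles[f"{c}.{signal}.autosomal"])
                for c in _PROBE_CLASSES]
        vecs = [v for v in vecs if v.size]
        return float(np.median(np.concatenate(vecs))) if vecs else np.nan

    ratio = pd.Series(
        [np.log2(max(med_signal(qc, "meth"), 1e-9) / max(med_signal(qc, "unmeth"), 1e-9))
         for qc in qc_objects], index=ids)
    ctrl = build_control_matrix(qc_objects)
    red = ctrl.loc[list(NORMALIZATION_CONTROL_TYPES["red"])].mean(axis=0)
    grn = ctrl.loc[list(NORMALIZATION_CONTROL_TYPES["grn"])].mean(axis=0)
    dye = np.log2(red / grn)

    ctrl_z_outlier = pd.Series(False, index=ids)
    for ct in CONTROL_TYPES:
        ctrl_z_outlier |= flag_outliers(ctrl.loc[ct], thr.outlier_sd)

    if n_probes is None:
        n_probes = max(len(qc.detection_fail | qc.bead_fail) for qc in qc_objects)
        n_probes = max(n_probes, 1)
        # best effort when the assay size is unknown; callers should pass it
        n_probes = max(n_probes, max(len(qc.detection_fail) for qc in qc_objects) * 20 or 1)
    det_frac = pd.Series([len(qc.detection_fail) / n_probes for qc in qc_objects], index=ids)
    bead_frac = pd.Series([len(qc.bead_fail) / n_probes for qc in qc_objects], index=ids)

    declared = pd.Series({qc.sample_id: (declared_sex or {}).get(
        qc.sample_id, qc.batch.get("sex", "")) for qc in qc_objects})
    predicted = pd.Series({qc.sample_id: qc.predicted_sex for qc in qc_objects})
    sex_mismatch = (declared != "") & (predicted != "U") & (declared != predicted)

    table = pd.DataFrame({
        "log2_meth_unmeth_ratio": ratio,
        "log2_dye_ratio": dye,
        "undetected_fraction": det_frac,
        "low_bead_fraction": bead_frac,
        "declared_sex": declared,
        "predicted_sex": predicted,
        "meth_unmeth_ratio": flag_outliers(ratio, thr.outlier_sd),
        "dye_bias": flag_outliers(dye, thr.outlier_sd),
        "control_outlier": ctrl_z_outlier,
        "detection_fraction": det_frac > thr.max_undetected_frac,
        "bead_fraction": bead_frac > thr.max_bead_frac,
        "sex_mismatch": sex_mismatch,
    })

    fail_counts: dict[str, int] = {}
    for qc in qc_objects:
        for pid in qc.detection_fail | qc.bead_fail:
            fail_counts[pid] = fail_counts.get(pid, 0) + 1
    n = len(qc_objects)
    exclusions = sorted(p for p, c in fail_counts.items() if c / n > thr.probe_fail_frac)
    return SampleQCReport(sample_table=table, probe_exclusions=exclusions, thresholds=thr)


# ---------------------------------------------------------------------------
# SNP concordance (sample-swap detection)
# ---------------------------------------------------------------------------


def snp_concordance(snp_betas: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per sample-pair fraction of SNPs whose beta-derived genotype call
    matches the genotype array.

    ``snp_betas``: samples x SNPs beta values; ``genotypes``: samples x SNPs
    in {0, 1, 2}.  Calls threshold betas at 1/3 and 2/3.  Returns a matrix
    (methylation samples x genotype samples); matched pairs sit near 1.
    """
    shared = snp_betas.columns.intersection(genotypes.columns)
    if len(shared) == 0:
        raise ValueError("no shared SNP probes between betas and genotypes")
    calls = pd.DataFrame(
        np.digitize(snp_betas[shared].to_numpy(), [1.0 / 3.0, 2.0 / 3.0]),
        index=snp_betas.index, columns=shared)
    g = genotypes[shared]
    out = pd.DataFrame(index=snp_betas.index, columns=genotypes.index, dtype=float)
    for gi in genotypes.index:
        out[gi] = (calls.to_numpy() == g.loc[gi].to_numpy()[None, :]).mean(axis=1)
    return out
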