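"""Synthetic Infinium-like array data with known planted structure.

Every downstream stage (QC, functional normalization, federated
normalization, EWAS) is testable without downloads: the generator emits raw
two-channel datasets whose technical components, slide/plate batch shifts,
sample sex, SNP genotypes and (optionally) cell mixtures are recorded in a
:class:`TruthRecord` for recovery tests.

Intensity model
---------------
Per-probe log-normal baselines (a total-intensity draw split into
methylated/unmethylated parts by a bimodal true beta), plus additive
technical-component loadings, additive slide/plate shifts, and Gaussian
noise; intensities are floored at 1.  Technical components load on both the
control probes and the assay-probe quantiles (each probe-class/signal subset
gets its own loading vector), so control-probe principal components are
informative about quantile variation — the premise of functional
normalization.  Slide and plate shifts are applied to assay probes only,
emulating batch variation that the array controls do not capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    CONTROL_TYPES,
    CONTROL_TYPE_CHANNEL,
    Manifest,
    RawDataset,
    RawSample,
)

__all__ = [
    "PLATFORM_SLIDE_SIZE",
    "SimulationParams",
    "TruthRecord",
    "make_manifest",
    "simulate_dataset",
    "make_cell_reference",
]

#: Samples per glass slide (bead chip): 12 for 450k-style, 8 for EPIC-style.
PLATFORM_SLIDE_SIZE = {"450k-like": 12, "EPIC-like": 8}

#: Slides per bisulfite-conversion plate (96-well plate).
_SLIDES_PER_PLATE = 8

# Control-type families measuring background get low baselines; the rest sit
# at assay-probe scale.
_BACKGROUND_CONTROL_FAMILIES = ("negative.", "background", ".bkg")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a synthetic cohort.

    ``k_true`` technical components load on controls and probe quantiles with
    geometrically decreasing scale (ratio 0.8), so components are planted
    with distinct variances.  ``slide_effect_sd`` / ``plate_effect_sd`` are
    additive intensity shifts shared by all assay probes of a batch group.
    """

    n_samples: int = 24
    platform: str = "450k-like"
    n_cpg_probes: int = 2000
    n_snp_probes: int = 20
    n_control_per_type: int = 15
    k_true: int = 2
    slide_effect_sd: float = 100.0
    plate_effect_sd: float = 50.0
    sex_ratio: float = 0.5
    noise_sd: float = 50.0
    seed: int = 0
    component_intensity: float = 800.0  # intensity-unit scale of component 1
    # log-sd of the per-sample red-channel dye factor.  Dye imbalance leaks a
    # sqrt(dye) scale factor through per-sample dye-bias correction, i.e. an
    # extra technical component beyond k_true; it is therefore off by default
    # so the planted technical dimension is exactly k_true.
    dye_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_SLIDE_SIZE:
            raise ValueError(f"unknown platform {self.platform!r}; "
                             f"expected one of {sorted(PLATFORM_SLIDE_SIZE)}")
        for name in ("n_samples", "n_cpg_probes", "n_snp_probes",
                     "n_control_per_type", "k_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")

    @property
    def slide_size(self) -> int:
        return PLATFORM_SLIDE_SIZE[self.platform]


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery tests."""

    technical_scores: pd.DataFrame  # samples x k_true
    slide_assignment: pd.Series  # sample -> slide id
    plate_assignment: pd.Series  # sample -> plate id
    true_sex: pd.Series  # sample -> {"F", "M"}
    snp_genotypes: pd.DataFrame  # samples x snps, values {0,1,2}
    cell_weights: Optional[pd.DataFrame] = None

    def validate(self, slide_size: int) -> None:
        counts = self.slide_assignment.value_counts()
        full = counts.iloc[:-1] if len(counts) > 1 else counts
        if len(self.slide_assignment) % slide_size == 0:
            full = counts
        if not (full == slide_size).all() and len(counts) > 1:
            # every slide except possibly the last must be full
            sizes = self.slide_assignment.groupby(self.slide_assignment).size()
            bad = sizes.iloc[:-1][sizes.iloc[:-1] != slide_size]
            if len(bad):
                raise ValueError(f"non-full interior slides: {dict(bad)}")
        if self.cell_weights is not None:
            w = self.cell_weights.to_numpy()
            if (w < 0).any() or not np.allclose(w.sum(axis=1), 1.0):
                raise ValueError("cell_weights rows must be a simplex")


# ---------------------------------------------------------------------------
# Manifest construction
# ---------------------------------------------------------------------------

# Deterministic cycles: ~70% Type II, 15% Type I grn, 15% Type I red;
# chromosomes mostly autosomal with X and Y interleaved so every
# (probe class, chromosome group) subset is populated.
_TYPE_CYCLE = (["II"] * 7 + ["I-grn"] + ["II"] * 7 + ["I-red"]) * 1 + ["I-grn", "I-red", "II", "II"]
_CHROM_CYCLE = [str(1 + (i % 22)) for i in range(44)] + ["X", "X", "X", "Y"]


def make_manifest(platform: str, params: SimulationParams) -> Manifest:
    """Build the probe dictionary for a simulated array.

    Lists Type I grn/red and Type II cpg probes across autosomes, X and Y,
    SNP probes, and ``n_control_per_type`` probes for each of the 42 control
    types.  Deterministic in its arguments.
    """
    if platform not in PLATFORM_SLIDE_SIZE:
        raise ValueError(f"unknown platform {platform!r}")
    if params.n_cpg_probes <= 0:
        raise ValueError("n_cpg_probes must be positive: an array needs assayable probes")

    rows: list[tuple] = []
    for i in range(params.n_cpg_probes):
        ptype = _TYPE_CYCLE[i % len(_TYPE_CYCLE)]
        chrom = _CHROM_CYCLE[i % len(_CHROM_CYCLE)]
        if ptype == "II":
            probe_type, channel = "II", "both"
        else:
            probe_type, channel = "I", ("grn" if ptype == "I-grn" else "red")
        rows.append((f"cg{i:08d}", probe_type, channel, "cpg", None, chrom))
    for j in range(params.n_snp_probes):
        rows.append((f"rs{j:06d}", "II", "both", "snp", None, str(1 + (j % 22))))
    for ct in CONTROL_TYPES:
        channel = CONTROL_TYPE_CHANNEL[ct]
        ptype = "II" if channel == "both" else "I"
        for r in range(params.n_control_per_type):
            rows.append((f"ctrl.{ct}.{r}", ptype, channel, "control", ct, "1"))
    df = pd.DataFrame(rows, columns=["probe_id", "probe_type", "channel",
                                     "target", "control_type", "chromosome"])
    return Manifest(df)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------


#: Control probes are replicate assays of synthetic templates and so have a
#: much tighter spread than biological probes.
_CONTROL_NOISE_SD = 20.0


def _component_scales(params: SimulationParams) -> np.ndarray:
    # distinct variances (ratio 0.8) keep planted components identifiable in
    # the control-matrix PCA without driving the weakest loadings into the
    # control noise floor
    return params.component_intensity * 0.8 ** np.arange(params.k_true)


def simulate_dataset(manifest: Manifest, params: SimulationParams
                     ) -> tuple[RawDataset, TruthRecord]:
    """Simulate a raw cohort on ``manifest`` under ``params`` (seeded)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    if n <= 0:
        raise ValueError("n_samples must be positive")
    slide_size = params.slide_size

    sample_ids = [f"S{i:04d}" for i in range(n)]
    slide = pd.Series([f"slide{i // slide_size:03d}" for i in range(n)], index=sample_ids)
    plate_size = slide_size * _SLIDES_PER_PLATE
    plate = pd.Series([f"plate{i // plate_size:02d}" for i in range(n)], index=sample_ids)
    row = pd.Series([f"R{i % slide_size + 1:02d}" for i in range(n)], index=sample_ids)

    sex = pd.Series(
        np.where(rng.random(n) < params.sex_ratio, "F", "M"), index=sample_ids
    )
    scores = rng.standard_normal((n, params.k_true))
    tech = pd.DataFrame(scores, index=sample_ids,
                        columns=[f"comp{k+1}" for k in range(params.k_true)])

    mtab = manifest.table
    assay = mtab[mtab["target"].isin(["cpg", "snp"])].reset_index(drop=True)
    assay_ids = assay["probe_id"].to_numpy()
    n_assay = len(assay)
    is_snp = (assay["target"] == "snp").to_numpy()
    chrom = assay["chromosome"].to_numpy()
    is_y = chrom == "Y"
    is_x = chrom == "X"

    # ---- per-probe baselines -------------------------------------------
    total = np.exp(rng.normal(np.log(4000.0), 0.5, n_assay))
    hi = rng.random(n_assay) < 0.5
    true_beta = np.where(hi, rng.beta(8, 2, n_assay), rng.beta(2, 8, n_assay))
    # SNP probes: trimodal betas from genotypes, filled in below
    base_meth = total * true_beta
    base_unmeth = total * (1.0 - true_beta)

    # ---- technical component loadings ----------------------------------
    scales = _component_scales(params)
    # one loading vector per (probe class, signal) subset
    class_key = np.where(assay["probe_type"] == "II", "II",
                         np.where(assay["channel"] == "grn", "I-grn", "I-red"))
    classes = ("I-grn", "I-red", "II")
    load_meth = {c: rng.standard_normal(params.k_true) * scales for c in classes}
    load_unmeth = {c: rng.standard_normal(params.k_true) * scales for c in classes}

    # component shifts scale with probe brightness (dim probes drift less),
    # so low-intensity probes never saturate at the intensity floor and each
    # quantile index stays linear in the component scores
    shift_meth = np.zeros((n_assay, n))
    shift_unmeth = np.zeros((n_assay, n))
    for c in classes:
        mask = class_key == c
        if params.k_true and mask.any():
            # capped at 2x so extreme-order-statistic quantiles do not get
            # runaway component leverage
            rel_m = np.minimum(base_meth[mask] / base_meth[mask].mean(), 2.0)
            rel_u = np.minimum(base_unmeth[mask] / base_unmeth[mask].mean(), 2.0)
            shift_meth[mask] += rel_m[:, None] * (scores @ load_meth[c])[None, :]
            shift_unmeth[mask] += rel_u[:, None] * (scores @ load_unmeth[c])[None, :]

    # ---- batch shifts (assay probes only; controls stay clean) ---------
    slide_shift = {s: rng.normal(0.0, params.slide_effect_sd)
                   for s in slide.unique()} if params.slide_effect_sd > 0 else {}
    plate_shift = {p: rng.normal(0.0, params.plate_effect_sd)
                   for p in plate.unique()} if params.plate_effect_sd > 0 else {}
    batch_vec = np.array([slide_shift.get(slide.iloc[i], 0.0)
                          + plate_shift.get(plate.iloc[i], 0.0) for i in range(n)])

    meth = base_meth[:, None] + shift_meth + batch_vec[None, :]
    unmeth = base_unmeth[:, None] + shift_unmeth + batch_vec[None, :]
    meth = meth + rng.normal(0.0, params.noise_sd, (n_assay, n))
    unmeth = unmeth + rng.normal(0.0, params.noise_sd, (n_assay, n))

    # ---- SNP genotypes --------------------------------------------------
    snp_ids = assay_ids[is_snp]
    maf = rng.uniform(0.2, 0.5, is_snp.sum())
    geno = (rng.random((n, is_snp.sum())) < maf).astype(int) + \
           (rng.random((n, is_snp.sum())) < maf).astype(int)
    snp_beta_levels = np.array([0.05, 0.5, 0.95])
    snp_total = total[is_snp]
    snp_betas = snp_beta_levels[geno] + rng.normal(0.0, 0.01, geno.shape)  # n x n_snp
    meth[is_snp, :] = (snp_total[:, None] * snp_betas.T
                       + rng.normal(0.0, params.noise_sd, (is_snp.sum(), n)))
    unmeth[is_snp, :] = (snp_total[:, None] * (1.0 - snp_betas.T)
                         + rng.normal(0.0, params.noise_sd, (is_snp.sum(), n)))
    genotypes = pd.DataFrame(geno, index=sample_ids, columns=snp_ids)

    # ---- per-sample channel background and dye imbalance ---------------
    # optical background is constant across samples (probe-level scatter is
    # still simulated), so the control matrix's structure beyond the planted
    # components is pure measurement noise
    bg_grn = np.full(n, 100.0)
    bg_red = np.full(n, 110.0)
    dye = np.exp(rng.normal(0.0, params.dye_sd, n))  # multiplies the red channel

    # ---- sex signal -----------------------------------------------------
    # females: chrY probes carry ~no signal (observed intensity collapses to
    # the channel background, i.e. negative-control scale); males: chrX halved
    female = (sex == "F").to_numpy()
    n_y = int(is_y.sum())
    n_x = int(is_x.sum())
    if n_y and female.any():
        nf = int(female.sum())
        meth[np.ix_(is_y, female)] = np.maximum(rng.normal(40.0, 15.0, (n_y, nf)), 0.0)
        unmeth[np.ix_(is_y, female)] = np.maximum(rng.normal(40.0, 15.0, (n_y, nf)), 0.0)
    if n_x and (~female).any():
        meth[np.ix_(is_x, ~female)] *= 0.5
        unmeth[np.ix_(is_x, ~female)] *= 0.5

    # ---- observed = signal + channel background, then dye imbalance -----
    # Type I probes read both alleles in their own channel; Type II reads
    # meth in green and unmeth in red.
    meth_bg = np.where((class_key == "I-red")[:, None], bg_red[None, :], bg_grn[None, :])
    unmeth_bg = np.where((class_key == "I-grn")[:, None], bg_grn[None, :], bg_red[None, :])
    meth = meth + meth_bg
    unmeth = unmeth + unmeth_bg

    red_rows = class_key == "I-red"
    meth[red_rows, :] *= dye[None, :]
    unmeth[red_rows, :] *= dye[None, :]
    unmeth[class_key == "II", :] *= dye[None, :]

    meth = np.maximum(meth, 1.0)
    unmeth = np.maximum(unmeth, 1.0)

    # ---- out-of-band: pure background in the opposite channel ----------
    t1_mask = (assay["probe_type"] == "I").to_numpy()
    t1_ids = assay_ids[t1_mask]
    t1_grn = (class_key == "I-grn")[t1_mask]  # oob measured in red
    n_t1 = int(t1_mask.sum())
    oob_m = np.empty((n_t1, n))
    oob_u = np.empty((n_t1, n))
    for arr in (oob_m, oob_u):
        noise = rng.normal(0.0, 20.0, (n_t1, n))
        arr[:] = np.where(t1_grn[:, None],
                          (bg_red * dye)[None, :], bg_grn[None, :]) + noise
    oob_m = np.maximum(oob_m, 1.0)
    oob_u = np.maximum(oob_u, 1.0)

    # ---- control probes -------------------------------------------------
    ctrl = mtab[mtab["target"] == "control"].reset_index(drop=True)
    ctrl_ids = ctrl["probe_id"].to_numpy()
    ctrl_types = ctrl["control_type"].to_numpy()
    n_ctrl = len(ctrl)
    type_index = {t: i for i, t in enumerate(CONTROL_TYPES)}
    is_bg_type = np.array([any(f in t for f in _BACKGROUND_CONTROL_FAMILIES)
                           for t in ctrl_types])
    # background families sit just above the optical background; the rest at
    # assay scale
    type_base = np.where(is_bg_type, 60.0, 5000.0)

    ctrl_base = type_base * np.exp(rng.normal(0.0, 0.2, n_ctrl))  # per probe
    # every control type responds to every component, with magnitude bounded
    # away from zero and proportional to the type's intensity scale, so the
    # standardized control matrix has no near-pure-noise rows diluting the
    # component subspace
    type_levels = np.where(
        np.array([any(f in t for f in _BACKGROUND_CONTROL_FAMILIES)
                  for t in CONTROL_TYPES]), 60.0, 5000.0)
    # fixed magnitude, random sign: every control row carries the same
    # per-component loading strength, so the standardized control matrix is
    # homoscedastic and its top-k principal components are a sufficient
    # summary of the planted scores
    ctrl_load = (rng.choice([-1.0, 1.0], (len(CONTROL_TYPES), params.k_true))
                 * scales[None, :] * (type_levels / 5000.0)[:, None])
    # planted components are dye-balanced: all four normalization-control
    # families share one loading vector, so the red/green ratio used by the
    # dye-bias correction is component-free (channel asymmetry is modelled
    # separately by dye_sd)
    norm_rows = [type_index[t] for t in ("norm.A", "norm.T", "norm.C", "norm.G")]
    if params.k_true:
        ctrl_load[norm_rows, :] = ctrl_load[norm_rows[0], :]
    ctrl_load_rows = ctrl_load[[type_index[t] for t in ctrl_types], :]
    ctrl_channel = np.array([CONTROL_TYPE_CHANNEL[t] for t in ctrl_types])
    bg_per_sample = np.where(ctrl_channel[:, None] == "red",
                             bg_red[None, :], bg_grn[None, :])
    ctrl_noise_sd = np.where(is_bg_type, _CONTROL_NOISE_SD / 4.0, _CONTROL_NOISE_SD)
    ctrl_int = (bg_per_sample + ctrl_base[:, None] + ctrl_load_rows @ scores.T
                + rng.normal(0.0, 1.0, (n_ctrl, n)) * ctrl_noise_sd[:, None])
    ctrl_int = np.where((ctrl_channel == "red")[:, None], ctrl_int * dye[None, :], ctrl_int)
    ctrl_int = np.maximum(ctrl_int, 1.0)

    # ---- bead counts ----------------------------------------------------
    beads = np.maximum(rng.poisson(15.0, (n_assay, n)), 1)
    low = rng.random((n_assay, n)) < 0.001
    beads = np.where(low, rng.integers(1, 3, (n_assay, n)), beads)

    samples: list[RawSample] = []
    assay_index = pd.Index(assay_ids)
    ctrl_index = pd.Index(ctrl_ids)
    t1_index = pd.Index(t1_ids)
    for i, sid in enumerate(sample_ids):
        samples.append(RawSample(
            sample_id=sid,
            meth=pd.Series(meth[:, i], index=assay_index),
            unmeth=pd.Series(unmeth[:, i], index=assay_index),
            oob=pd.DataFrame({"meth": oob_m[:, i], "unmeth": oob_u[:, i]}, index=t1_index),
            control_intensities=pd.Series(ctrl_int[:, i], index=ctrl_index),
            bead_counts=pd.Series(beads[:, i], index=assay_index),
            batch={"slide": slide.iloc[i], "plate": plate.iloc[i],
                   "row": row.iloc[i], "sex": sex.iloc[i]},
        ))
    dataset = RawDataset(manifest=manifest, samples=samples)
    truth = TruthRecord(
        technical_scores=tech,
        slide_assignment=slide,
        plate_assignment=plate,
        true_sex=sex,
        snp_genotypes=genotypes,
    )
    return dataset, truth


def write_truth(truth: TruthRecord, path) -> None:
    """Emit the ground truth as sidecar TSV + JSON next to a dataset."""
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.technical_scores.to_csv(path / "truth_scores.tsv", sep="\t")
    truth.snp_genotypes.to_csv(path / "truth_genotypes.tsv", sep="\t")
    meta = pd.DataFrame({
        "slide": truth.slide_assignment,
        "plate": truth.plate_assignment,
        "sex": truth.true_sex,
    })
    meta.to_csv(path / "truth_samples.tsv", sep="\t")
    import json
    (path / "truth.json").write_text(json.dumps(
        {"k_true": truth.technical_scores.shape[1],
         "n_samples": len(truth.slide_assignment)}) + "\n")


# ---------------------------------------------------------------------------
# Synthetic cell-type reference
# ---------------------------------------------------------------------------


def make_cell_reference(n_cell_types: int, n_probes: int, seed: int):
    """Synthetic stand-in for a blood cell-type methylation reference.

    Each cell type gets a distinctive beta profile: a shared bimodal
    baseline plus cell-type-specific discriminating probes, so pairwise
    profiles differ by >= 0.1 mean absolute beta on their discriminating
    probes.  Returns a :class:`methylfn.ewas.CellReference`.
    """
    from .ewas import CellReference

    if n_cell_types < 2:
        raise ValueError("a cell-type reference needs at least 2 cell types")
    if n_probes < n_cell_types:
        raise ValueError("need at least as many probes as cell types")
    rng = np.random.default_rng(seed)
    hi = rng.random(n_probes) < 0.5
    baseline = np.where(hi, rng.beta(8, 2, n_probes), rng.beta(2, 8, n_probes))
    betas = np.tile(baseline[:, None], (1, n_cell_types))
    # each cell type flips its own block of discriminating probes
    block = max(1, n_probes // (2 * n_cell_types))
    for j in range(n_cell_types):
        idx = np.arange(j * block, (j + 1) * block) % n_probes
        betas[idx, j] = 1.0 - betas[idx, j]
    betas = np.clip(betas + rng.normal(0.0, 0.02, betas.shape), 0.0, 1.0)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    cell_types = [f"cell{j+1}" for j in range(n_cell_types)]
    return CellReference(
        betas=pd.DataFrame(betas, index=probe_ids, columns=cell_types)
    )
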