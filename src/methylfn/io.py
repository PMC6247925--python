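"""Data model and exchange formats for Infinium-style methylation data.

The package works on a small set of containers:

``Manifest``
    The probe dictionary: probe id, Infinium chemistry type (I/II), colour
    channel, target class (cpg / snp / control), control category and
    chromosome.

``RawSample`` / ``RawDataset``
    Per-sample two-channel intensities (methylated / unmethylated), the
    out-of-band signal of Type I probes (pure background, used by noob),
    control-probe intensities, bead counts and batch labels.

Datasets are exchanged as a directory of gzip-compressed TSV tables plus a
JSON descriptor — inspectable, language-neutral and bit-exact (floats are
serialized with shortest round-trip decimals).
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_TYPES",
    "CONTROL_TYPE_CHANNEL",
    "NEGATIVE_CONTROL_TYPES",
    "NORMALIZATION_CONTROL_TYPES",
    "Manifest",
    "RawSample",
    "RawDataset",
    "DatasetFormatError",
    "write_dataset",
    "read_dataset",
    "merge_platforms",
]


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset is malformed or inconsistent."""


# ---------------------------------------------------------------------------
# Control-type convention
# ---------------------------------------------------------------------------
# Illumina summarises array controls into named categories (bisulfite
# conversion, extension, hybridization, specificity, staining, target
# removal, negative, normalization, ...).  The package convention is this
# fixed list of 42 categories; real-manifest ingestion must map vendor
# categories onto it.  The negative.* and norm.* families are load-bearing:
# negative controls drive detection p-values, normalization controls drive
# dye-bias correction.

CONTROL_TYPES: tuple[str, ...] = (
    "bisulfite.conversion.I.grn",
    "bisulfite.conversion.I.red",
    "bisulfite.conversion.II",
    "bisulfite.conversion.I.unconverted.grn",
    "bisulfite.conversion.I.unconverted.red",
    "bisulfite.conversion.II.unconverted",
    "extension.A",
    "extension.T",
    "extension.C",
    "extension.G",
    "extension.background.grn",
    "extension.background.red",
    "hybridization.low",
    "hybridization.medium",
    "hybridization.high",
    "hybridization.background",
    "specificity.I.grn",
    "specificity.I.red",
    "specificity.II",
    "specificity.I.mismatch.grn",
    "specificity.I.mismatch.red",
    "specificity.II.mismatch",
    "staining.biotin",
    "staining.biotin.background",
    "staining.dnp",
    "staining.dnp.background",
    "staining.background.grn",
    "staining.background.red",
    "target.removal.1",
    "target.removal.2",
    "non.polymorphic.A",
    "non.polymorphic.T",
    "non.polymorphic.C",
    "non.polymorphic.G",
    "negative.grn",
    "negative.red",
    "norm.A",
    "norm.T",
    "norm.C",
    "norm.G",
    "restoration",
    "dye.bias.check",
)

assert len(CONTROL_TYPES) == 42

# Channel a control category is read in.  A/T bases extend in red, C/G in
# green (Infinium chemistry); ambiguous categories are labelled "both".
_RED_TYPES = {
    "bisulfite.conversion.I.red",
    "bisulfite.conversion.I.unconverted.red",
    "extension.A",
    "extension.T",
    "extension.background.red",
    "specificity.I.red",
    "specificity.I.mismatch.red",
    "staining.dnp",
    "staining.dnp.background",
    "staining.background.red",
    "non.polymorphic.A",
    "non.polymorphic.T",
    "negative.red",
    "norm.A",
    "norm.T",
}
_GRN_TYPES = {
    "bisulfite.conversion.I.grn",
    "bisulfite.conversion.I.unconverted.grn",
    "extension.C",
    "extension.G",
    "extension.background.grn",
    "specificity.I.grn",
    "specificity.I.mismatch.grn",
    "staining.biotin",
    "staining.biotin.background",
    "staining.background.grn",
    "non.polymorphic.C",
    "non.polymorphic.G",
    "negative.grn",
    "norm.C",
    "norm.G",
    "restoration",
}

CONTROL_TYPE_CHANNEL: dict[str, str] = {
    name: ("red" if name in _RED_TYPES else "grn" if name in _GRN_TYPES else "both")
    for name in CONTROL_TYPES
}

NEGATIVE_CONTROL_TYPES = {"grn": "negative.grn", "red": "negative.red"}
#: norm.A/T are read in red, norm.C/G in green
NORMALIZATION_CONTROL_TYPES = {"red": ("norm.A", "norm.T"), "grn": ("norm.C", "norm.G")}

_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["probe_id", "probe_type", "channel", "target", "control_type", "chromosome"]


@dataclass(frozen=True)
class Manifest:
    """Probe dictionary for a dataset.

    Wraps a DataFrame with columns ``probe_id, probe_type, channel, target,
    control_type, chromosome``.  Type II probes read both channels; control
    probes carry a non-null ``control_type`` drawn from :data:`CONTROL_TYPES`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetFormatError(f"manifest missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
            raise DatasetFormatError(f"duplicate probe ids in manifest: {dups}")
        bad_type2 = df[(df["probe_type"] == "II") & (df["channel"] != "both")]
        if len(bad_type2):
            raise DatasetFormatError(
                f"Type II probes must have channel='both': {bad_type2['probe_id'].tolist()[:5]}"
            )
        ctrl = df[df["target"] == "control"]
        if ctrl["control_type"].isna().any():
            raise DatasetFormatError("control probes must carry a control_type")
        unknown = set(ctrl["control_type"]) - set(CONTROL_TYPES)
        if unknown:
            raise DatasetFormatError(f"unknown control types: {sorted(unknown)}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    # -- convenience views -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def probes(self, target: str | None = None) -> pd.DataFrame:
        if target is None:
            return self.table
        return self.table[self.table["target"] == target]

    @property
    def assay_probe_ids(self) -> pd.Index:
        """Ids of probes carrying meth/unmeth signal (cpg + snp)."""
        m = self.table["target"].isin(["cpg", "snp"])
        return pd.Index(self.table.loc[m, "probe_id"])

    @property
    def control_probe_ids(self) -> pd.Index:
        return pd.Index(self.probes("control")["probe_id"])

    def control_probes_of_type(self, control_type: str) -> pd.Index:
        t = self.probes("control")
        return pd.Index(t.loc[t["control_type"] == control_type, "probe_id"])

    def type1_probe_ids(self, channel: str) -> pd.Index:
        t = self.table
        m = (t["probe_type"] == "I") & (t["channel"] == channel) & t["target"].isin(["cpg", "snp"])
        return pd.Index(t.loc[m, "probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    def equals(self, other: "Manifest") -> bool:
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# RawSample / RawDataset
# ---------------------------------------------------------------------------


@dataclass
class RawSample:
    """Two-channel raw intensities for one array.

    ``meth`` / ``unmeth`` are indexed by assay (cpg + snp) probe id.  ``oob``
    holds the out-of-band signal of Type I probes — the intensity measured in
    the channel the probe does *not* report in, which is pure background —
    as a DataFrame with columns ``meth, unmeth`` indexed by Type I probe id.
    """

    sample_id: str
    meth: pd.Series
    unmeth: pd.Series
    oob: pd.DataFrame
    control_intensities: pd.Series
    bead_counts: pd.Series
    batch: dict[str, str] = field(default_factory=dict)

    def validate(self, manifest: Manifest) -> None:
        assay = manifest.assay_probe_ids
        for name, series in (("meth", self.meth), ("unmeth", self.unmeth)):
            missing = assay.difference(series.index)
            if len(missing):
                raise DatasetFormatError(
                    f"sample {self.sample_id}: {name} missing probes {list(missing[:5])}"
                )
            extra = series.index.difference(manifest.probe_ids)
            if len(extra):
                raise DatasetFormatError(
                    f"sample {self.sample_id}: {name} has probes absent from manifest: "
                    f"{list(extra[:5])}"
                )
        extra_ctrl = self.control_intensities.index.difference(manifest.control_probe_ids)
        if len(extra_ctrl):
            raise DatasetFormatError(
                f"sample {self.sample_id}: control intensities for unknown probes "
                f"{list(extra_ctrl[:5])}"
            )
        if (self.bead_counts < 0).any():
            raise DatasetFormatError(f"sample {self.sample_id}: negative bead counts")


@dataclass
class RawDataset:
    """A manifest plus an ordered list of samples sharing it."""

    manifest: Manifest
    samples: list[RawSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetFormatError(f"duplicate sample ids: {dup}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def validate(self) -> None:
        for s in self.samples:
            s.validate(self.manifest)

    def get_sample(self, sample_id: str) -> RawSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Exchange format
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1
_COMPONENTS = ("manifest", "meth", "unmeth", "oob_meth", "oob_unmeth", "controls", "beadcounts", "batches")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # str() of a float is the shortest round-trip decimal in py3 -> bit-exact
    with gzip.open(path, "wt", newline="") as fh:
        df.to_csv(fh, sep="\t", index=True)


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise DatasetFormatError(f"missing component file: {path.name}")
    try:
        with gzip.open(path, "rt") as fh:
            return pd.read_csv(fh, sep="\t", index_col=0,
                               float_precision="round_trip", **kw)
    except (OSError, EOFError, pd.errors.ParserError) as exc:
        raise DatasetFormatError(f"corrupt component file {path.name}: {exc}") from exc


def write_dataset(dataset: RawDataset, path: str | Path) -> Path:
    """Write a dataset as a directory of gzipped TSVs plus a JSON descriptor."""
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest_df = dataset.manifest.table
    ids = dataset.sample_ids

    assay = dataset.manifest.assay_probe_ids
    meth = pd.DataFrame({s.sample_id: s.meth.reindex(assay) for s in dataset.samples})
    unmeth = pd.DataFrame({s.sample_id: s.unmeth.reindex(assay) for s in dataset.samples})
    oob_index = dataset.samples[0].oob.index
    oob_meth = pd.DataFrame({s.sample_id: s.oob["meth"].reindex(oob_index) for s in dataset.samples})
    oob_unmeth = pd.DataFrame(
        {s.sample_id: s.oob["unmeth"].reindex(oob_index) for s in dataset.samples}
    )
    ctrl = pd.DataFrame(
        {s.sample_id: s.control_intensities.reindex(dataset.manifest.control_probe_ids)
         for s in dataset.samples}
    )
    beads = pd.DataFrame({s.sample_id: s.bead_counts.reindex(assay) for s in dataset.samples})
    batches = pd.DataFrame({s.sample_id: pd.Series(s.batch, dtype=object) for s in dataset.samples})

    _write_tsv(manifest_df.set_index("probe_id"), path / "manifest.tsv.gz")
    _write_tsv(meth, path / "meth.tsv.gz")
    _write_tsv(unmeth, path / "unmeth.tsv.gz")
    _write_tsv(oob_meth, path / "oob_meth.tsv.gz")
    _write_tsv(oob_unmeth, path / "oob_unmeth.tsv.gz")
    _write_tsv(ctrl, path / "controls.tsv.gz")
    _write_tsv(beads, path / "beadcounts.tsv.gz")
    _write_tsv(batches, path / "batches.tsv.gz")

    descriptor = {
        "format": "methylfn-dataset",
        "version": _FORMAT_VERSION,
        "n_samples": len(ids),
        "sample_ids": ids,
        "n_probes": len(manifest_df),
        "components": list(_COMPONENTS),
    }
    (path / "dataset.json").write_text(json.dumps(descriptor, indent=1) + "\n")
    return path


def read_dataset(path: str | Path) -> RawDataset:
    """Read a dataset written by :func:`write_dataset` (bit-exact round trip)."""
    path = Path(path)
    desc_path = path / "dataset.json"
    if not desc_path.exists():
        raise DatasetFormatError(f"not a dataset directory (no dataset.json): {path}")
    try:
        descriptor = json.loads(desc_path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"malformed dataset.json: {exc}") from exc
    if descriptor.get("format") != "methylfn-dataset":
        raise DatasetFormatError("dataset.json does not describe a methylfn dataset")

    manifest_df = _read_tsv(path / "manifest.tsv.gz", dtype=str).reset_index()
    manifest_df["control_type"] = manifest_df["control_type"].where(
        manifest_df["control_type"].notna(), None
    )
    manifest = Manifest(manifest_df)

    meth = _read_tsv(path / "meth.tsv.gz")
    unmeth = _read_tsv(path / "unmeth.tsv.gz")
    oob_meth = _read_tsv(path / "oob_meth.tsv.gz")
    oob_unmeth = _read_tsv(path / "oob_unmeth.tsv.gz")
    ctrl = _read_tsv(path / "controls.tsv.gz")
    beads = _read_tsv(path / "beadcounts.tsv.gz")
    batches = _read_tsv(path / "batches.tsv.gz", dtype=str)

    ids = descriptor["sample_ids"]
    for name, df in (("meth", meth), ("unmeth", unmeth), ("controls", ctrl), ("beadcounts", beads)):
        if list(df.columns) != ids:
            raise DatasetFormatError(
                f"component {name} columns disagree with descriptor sample ids"
            )
        if descriptor["n_samples"] != len(df.columns):
            raise DatasetFormatError(f"component {name} truncated: sample count mismatch")
    assay = manifest.assay_probe_ids
    unknown = pd.Index(meth.index).difference(assay)
    if len(unknown):
        raise DatasetFormatError(
            f"meth table contains probes absent from manifest: {list(unknown[:5])}"
        )
    if len(meth) != len(assay):
        raise DatasetFormatError("meth table truncated: probe count disagrees with manifest")

    samples = []
    for sid in ids:
        oob = pd.DataFrame({"meth": oob_meth[sid], "unmeth": oob_unmeth[sid]})
        batch = {} if sid not in batches.columns else batches[sid].dropna().to_dict()
        samples.append(
            RawSample(
                sample_id=sid,
                meth=meth[sid],
                unmeth=unmeth[sid],
                oob=oob,
                control_intensities=ctrl[sid],
                bead_counts=beads[sid].astype(int),
                batch=batch,
            )
        )
    dataset = RawDataset(manifest=manifest, samples=samples)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# Multi-platform merging
# ---------------------------------------------------------------------------


def merge_platforms(datasets: Sequence[RawDataset]) -> RawDataset:
    """Merge datasets from different platforms on their common probes.

    The merged manifest is the intersection of the probe sets (identical
    methods are then applied to probes shared by both arrays); every sample
    is retained and its source platform recorded in the batch map.
    """
    if not datasets:
        raise ValueError("merge_platforms requires at least one dataset")
    if len(datasets) == 1:
        return datasets[0]

    shared = datasets[0].manifest.probe_ids
    for ds in datasets[1:]:
        shared = shared.intersection(ds.manifest.probe_ids)
    if len(shared) == 0:
        raise DatasetFormatError("empty probe intersection: datasets share no probes")

    # Conflicting probe definitions are an error: same id must mean the same
    # chemistry and channel on every platform.
    ref = datasets[0].manifest.table.set_index("probe_id").loc[shared]
    for ds in datasets[1:]:
        other = ds.manifest.table.set_index("probe_id").loc[shared]
        for col in ("probe_type", "channel", "target", "control_type"):
            neq = ref[col].fillna("") != other[col].fillna("")
            if neq.any():
                bad = list(ref.index[neq][:5])
                raise DatasetFormatError(f"conflicting probe definitions for {col}: {bad}")

    # Preserve the first manifest's probe ordering restricted to the intersection
    keep = datasets[0].manifest.table["probe_id"].isin(set(shared))
    merged_manifest = Manifest(datasets[0].manifest.table[keep].reset_index(drop=True))
    assay = merged_manifest.assay_probe_ids
    ctrl_ids = merged_manifest.control_probe_ids
    t1_ids = merged_manifest.table[
        (merged_manifest.table["probe_type"] == "I")
        & merged_manifest.table["target"].isin(["cpg", "snp"])
    ]["probe_id"]

    all_ids: set[str] = set()
    samples: list[RawSample] = []
    for idx, ds in enumerate(datasets):
        for s in ds.samples:
            sid = s.sample_id
            if sid in all_ids:
                sid = f"{s.sample_id}.{idx}"  # deterministic disambiguation
                warnings.warn(
                    f"sample id {s.sample_id!r} occurs in multiple datasets; "
                    f"renamed to {sid!r} in the merge"
                )
            all_ids.add(sid)
            batch = dict(s.batch)
            batch["source_platform"] = batch.get("source_platform", f"dataset{idx}")
            samples.append(
                RawSample(
                    sample_id=sid,
                    meth=s.meth.reindex(assay),
                    unmeth=s.unmeth.reindex(assay),
                    oob=s.oob.reindex(pd.Index(t1_ids)),
                    control_intensities=s.control_intensities.reindex(ctrl_ids),
                    bead_counts=s.bead_counts.reindex(assay),
                    batch=batch,
                )
            )
    return RawDataset(manifest=merged_manifest, samples=samples)
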