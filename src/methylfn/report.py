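"""Markdown + HTML reports and the end-to-end pipeline.

Reports are deterministic: regenerating from identical inputs yields
identical markdown bytes.  The pipeline runs QC -> normalization ->
(optional) EWAS with every intermediate artifact written to disk, so each
stage can be evaluated before proceeding; a stage failure halts with a
stage-named error and retains prior artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .io import RawDataset, read_dataset, write_dataset
from .qc import QCObject, QCThresholds, build_control_matrix, build_qc_object, sample_qc
from .normalize import normalize_dataset, select_pcs_cv
from .ewas import batch_association_tests, run_ewas
from .synthetic import SimulationParams, make_manifest, simulate_dataset, write_truth

__all__ = ["ReportBundle", "render_report", "PipelineConfig", "run_pipeline",
           "StageError", "df_to_markdown"]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def df_to_markdown(df: pd.DataFrame, float_fmt: str = "{:.6g}") -> str:
    """Deterministic pipe-table rendering (no external templating)."""
    def fmt(v) -> str:
        if isinstance(v, float):
            return float_fmt.format(v)
        return str(v)

    df = df.reset_index() if df.index.name or not isinstance(df.index, pd.RangeIndex) else df
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in rec) + " |"
            for rec in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


_REQUIRED_TABLES = {
    "qc": ("sample_flags", "probe_exclusions"),
    "normalization": ("batch_pre", "batch_post"),
    "ewas": ("model_summary", "top_associations"),
}


@dataclass
class ReportBundle:
    kind: Literal["qc", "normalization", "ewas"]
    tables: dict[str, pd.DataFrame]
    thresholds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__


def _markdown_to_html(md: str, title: str) -> str:
    lines = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
             f"<title>{title}</title>",
             "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
             "padding:2px 6px;font:12px monospace}</style></head><body>"]
    in_table = False
    for line in md.splitlines():
        if line.startswith("|"):
            cells = [c.strip() for c in line.strip("|").split("|")]
            if all(set(c) <= set(" -") for c in cells):
                continue
            tag = "th" if not in_table else "td"
            if not in_table:
                lines.append("<table>")
                in_table = True
            lines.append("<tr>" + "".join(f"<{tag}>{c}</{tag}>" for c in cells) + "</tr>")
        else:
            if in_table:
                lines.append("</table>")
                in_table = False
            if line.startswith("# "):
                lines.append(f"<h1>{line[2:]}</h1>")
            elif line.startswith("## "):
                lines.append(f"<h2>{line[3:]}</h2>")
            elif line:
                lines.append(f"<p>{line}</p>")
    if in_table:
        lines.append("</table>")
    lines.append("</body></html>")
    return "\n".join(lines) + "\n"


def render_report(bundle: ReportBundle, path: str | Path) -> tuple[Path, Path]:
    """Emit ``<kind>_report.md`` and ``.html``; errors name missing tables."""
    required = _REQUIRED_TABLES[bundle.kind]
    missing = [t for t in required if t not in bundle.tables]
    if missing:
        raise ValueError(f"{bundle.kind} report bundle missing tables: {missing}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    parts = [f"# {bundle.kind} report", "",
             f"Generated by methylfn {bundle.version}.", ""]
    if bundle.thresholds:
        parts += ["## Thresholds", "",
                  df_to_markdown(pd.DataFrame(
                      sorted(bundle.thresholds.items()),
                      columns=["threshold", "value"])), ""]
    for name in sorted(bundle.tables):
        df = bundle.tables[name]
        parts += [f"## {name}", ""]
        parts += [df_to_markdown(df) if len(df) else "(empty table)", ""]
    if bundle.input_digests:
        parts += ["## Input digests", "",
                  df_to_markdown(pd.DataFrame(
                      sorted(bundle.input_digests.items()),
                      columns=["input", "sha256"])), ""]
    md = "\n".join(parts)
    md_path = path / f"{bundle.kind}_report.md"
    html_path = path / f"{bundle.kind}_report.html"
    md_path.write_text(md)
    html_path.write_text(_markdown_to_html(md, f"{bundle.kind} report"))
    return md_path, html_path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = 24
    platform: str = "450k-like"
    n_cpg_probes: int = 2000
    n_snp_probes: int = 20
    n_control_per_type: int = 5
    k_true: int = 2
    slide_effect_sd: float = 100.0
    plate_effect_sd: float = 50.0
    sex_ratio: float = 0.5
    noise_sd: float = 50.0


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_q: int = 500
    detection_p: float = 0.01
    bead_threshold: int = 3
    outlier_sd: float = 3.0


class NormalizeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pcs: int | Literal["auto"] = 2
    pc_candidates: list[int] = [0, 1, 2, 3, 4, 5]
    folds: int = 10
    fixed_effects: list[str] = []
    random_effects: list[str] = []
    offset: float = 100.0


class EWASConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variable: str
    covariates: list[str] = []
    n_sv: int | Literal["auto"] = "auto"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str
    dataset: Optional[str] = None  # existing dataset directory; else simulate
    simulate: SimulateConfig = SimulateConfig()
    qc: QCConfig = QCConfig()
    normalize: NormalizeConfig = NormalizeConfig()
    ewas: Optional[EWASConfig] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")) if path.is_dir() else [path]:
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str | Path) -> dict[str, Path]:
    """Execute qc -> normalize -> (optional) ewas, writing all artifacts.

    Returns a map of artifact names to paths.  Failures raise
    :class:`StageError` naming the stage; artifacts from prior stages are
    retained on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # -- data ------------------------------------------------------------
    try:
        if config.dataset:
            dataset = read_dataset(config.dataset)
            truth = None
        else:
            params = SimulationParams(seed=config.seed,
                                      **config.simulate.model_dump())
            manifest = make_manifest(params.platform, params)
            dataset, truth = simulate_dataset(manifest, params)
            write_dataset(dataset, out / "dataset")
            write_truth(truth, out / "dataset")
            artifacts["dataset"] = out / "dataset"
    except Exception as exc:
        raise StageError("data", exc) from exc

    # -- qc ---------------------------------------------------------------
    try:
        thr = QCThresholds(detection_p=config.qc.detection_p,
                           bead_threshold=config.qc.bead_threshold,
                           outlier_sd=config.qc.outlier_sd)
        qcs = [build_qc_object(s, dataset.manifest, n_q=config.qc.n_q,
                               detection_p=thr.detection_p,
                               bead_threshold=thr.bead_threshold)
               for s in dataset.samples]
        report = sample_qc(qcs, thresholds=thr,
                           n_probes=len(dataset.manifest.assay_probe_ids))
        (out / "qc_objects.json").write_text(json.dumps(
            [qc.to_dict() for qc in qcs], sort_keys=True))
        artifacts["qc_objects"] = out / "qc_objects.json"
        bundle = ReportBundle(
            kind="qc",
            tables={
                "sample_flags": report.sample_table.reset_index(names="sample"),
                "probe_exclusions": pd.DataFrame(
                    {"probe_id": report.probe_exclusions}),
            },
            thresholds={k: getattr(thr, k) for k in
                        ("detection_p", "bead_threshold", "outlier_sd",
                         "max_undetected_frac", "max_bead_frac", "probe_fail_frac")},
        )
        md, html = render_report(bundle, out)
        artifacts["qc_report"] = md
    except StageError:
        raise
    except Exception as exc:
        raise StageError("qc", exc) from exc

    # -- normalize --------------------------------------------------------
    try:
        ncfg = config.normalize
        if ncfg.pcs == "auto":
            k, scree = select_pcs_cv(qcs, ncfg.pc_candidates,
                                     n_folds=min(ncfg.folds, len(qcs)),
                                     fixed=ncfg.fixed_effects or None,
                                     random=ncfg.random_effects or None,
                                     seed=config.seed)
            scree.to_csv(out / "scree.tsv", sep="\t", index=False)
            artifacts["scree"] = out / "scree.tsv"
        else:
            k = int(ncfg.pcs)
        result = normalize_dataset(dataset, k=k,
                                   fixed=ncfg.fixed_effects or None,
                                   random=ncfg.random_effects or None,
                                   n_q=config.qc.n_q, offset=ncfg.offset,
                                   qc_objects=qcs)
        result.betas.to_csv(out / "betas.tsv", sep="\t")
        artifacts["betas"] = out / "betas.tsv"
        (out / "normalized_quantiles.json").write_text(json.dumps(
            {sid: t.to_dict() for sid, t in sorted(result.targets.items())},
            sort_keys=True))
        artifacts["normalized_quantiles"] = out / "normalized_quantiles.json"

        batch_df = pd.DataFrame({s.sample_id: s.batch for s in dataset.samples}).T
        batch_df = batch_df[[c for c in ("slide", "plate", "row") if c in batch_df.columns]]
        raw_betas = pd.DataFrame({
            s.sample_id: s.meth / (s.meth + s.unmeth + ncfg.offset)
            for s in dataset.samples})
        pre_full, _ = batch_association_tests(raw_betas, batch_df)
        post_full, _ = batch_association_tests(result.betas, batch_df)
        bundle = ReportBundle(
            kind="normalization",
            tables={"batch_pre": pre_full[pre_full["test"] == "F"],
                    "batch_post": post_full[post_full["test"] == "F"]},
            thresholds={"pcs": k, "offset": ncfg.offset,
                        "random_effects": ",".join(ncfg.random_effects) or "-"},
        )
        md, html = render_report(bundle, out)
        artifacts["normalization_report"] = md
    except StageError:
        raise
    except Exception as exc:
        raise StageError("normalize", exc) from exc

    # -- ewas -------------------------------------------------------------
    if config.ewas is not None:
        try:
            ecfg = config.ewas
            pheno = pd.DataFrame({s.sample_id: s.batch for s in dataset.samples}).T
            if ecfg.variable not in pheno.columns:
                raise ValueError(f"ewas variable {ecfg.variable!r} not in batch table")
            variable = pheno[ecfg.variable]
            variable.name = ecfg.variable
            covs = pheno[ecfg.covariates] if ecfg.covariates else None
            ew = run_ewas(result.betas, variable, covariates=covs,
                          n_sv=ecfg.n_sv, seed=config.seed)
            for name, block in ew.blocks.items():
                block.to_csv(out / f"ewas_{name.replace('.', '_')}.tsv", sep="\t")
            artifacts["ewas_tables"] = out
            summary = pd.DataFrame(
                [{"model": name,
                  "n_bonferroni_hits": int((b["p_bonferroni"] < 0.05).sum()),
                  "min_p": float(b["p"].min())}
                 for name, b in ew.blocks.items()])
            top = ew.blocks["sva"].nsmallest(20, "p").reset_index(names="probe_id")
            bundle = ReportBundle(
                kind="ewas",
                tables={"model_summary": summary, "top_associations": top},
                thresholds={"variable": ecfg.variable, "n_sv": ew.metadata["n_sv"]},
            )
            md, html = render_report(bundle, out)
            artifacts["ewas_report"] = md
        except StageError:
            raise
        except Exception as exc:
            raise StageError("ewas", exc) from exc

    return artifacts
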