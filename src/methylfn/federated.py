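"""Multi-site normalization without sharing individual-level biology.

Control-probe summaries capture only technical variation, so a site can
export its per-sample QC objects (control summaries + intensity quantiles +
batch labels), a central server can fit the step-1 quantile model on the
pooled summaries, and each site can finalize its own samples locally from
the returned targets.  Because step-1 sorts samples canonically and step-2
touches one sample at a time, the federated result is bit-identical to a
pooled single-server run for any partition of samples into sites and any
processing order.

Transport is out of scope: the protocol is three file-exchange steps
(bundle out, targets in, betas local) and can ride any channel.  Every
message is schema-audited so that no probe-level methylation or phenotype
ever leaves a site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RawDataset
from .qc import (
    PrivacyError,
    QCObject,
    QCThresholds,
    audit_privacy,
    build_qc_object,
    sample_qc,
)
from .normalize import (
    NormalizedQuantiles,
    betas_for_sample,
    finalize_sample,
    fit_quantile_model,
)
from .qc import noob_correct

__all__ = [
    "SiteBundle",
    "export_site_summaries",
    "central_fit",
    "finalize_site",
    "bundle_to_json",
    "bundle_from_json",
    "targets_to_json",
    "targets_from_json",
]

_BUNDLE_SCHEMA = "methylfn.site-bundle/1"
_TARGETS_SCHEMA = "methylfn.normalized-quantiles/1"


@dataclass
class SiteBundle:
    """One site's exported summaries: QC objects only, schema-audited."""

    site_id: str
    qc_objects: list[QCObject] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"schema": _BUNDLE_SCHEMA, "site_id": self.site_id,
                "qc_objects": [qc.to_dict() for qc in self.qc_objects]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SiteBundle":
        if d.get("schema") != _BUNDLE_SCHEMA:
            raise PrivacyError(f"unexpected bundle schema: {d.get('schema')!r}")
        extra = set(d.keys()) - {"schema", "site_id", "qc_objects"}
        if extra:
            raise PrivacyError(f"disallowed fields in site bundle: {sorted(extra)}")
        qcs = [QCObject.from_dict(q) for q in d["qc_objects"]]  # audits each
        return cls(site_id=d["site_id"], qc_objects=qcs)


def audit_bundle(payload: Mapping) -> None:
    """Schema audit of a serialized bundle; raises PrivacyError on probe-level
    cpg fields anywhere in the payload."""
    SiteBundle.from_dict(payload)


def bundle_to_json(bundle: SiteBundle) -> str:
    return json.dumps(bundle.to_dict(), sort_keys=True)


def bundle_from_json(text: str) -> SiteBundle:
    return SiteBundle.from_dict(json.loads(text))


def export_site_summaries(dataset: RawDataset, site_id: str = "site",
                          n_q: int = 500,
                          thresholds: QCThresholds | None = None,
                          include_failed: bool = False) -> SiteBundle:
    """Build the site's QC objects and package them for the central fit.

    Samples failing hard QC (excess undetected probes / low beads, sex
    mismatch) abort the export unless ``include_failed`` overrides.
    """
    thr = thresholds or QCThresholds()
    qcs = [build_qc_object(s, dataset.manifest, n_q=n_q,
                           detection_p=thr.detection_p,
                           bead_threshold=thr.bead_threshold)
           for s in dataset.samples]
    report = sample_qc(qcs, thresholds=thr,
                       n_probes=len(dataset.manifest.assay_probe_ids))
    failed = report.failed_samples
    if failed and not include_failed:
        raise ValueError(
            f"site {site_id}: samples failed QC: {failed}; "
            "pass include_failed=True to export them anyway"
        )
    bundle = SiteBundle(site_id=site_id, qc_objects=qcs)
    audit_bundle(bundle.to_dict())
    return bundle


def central_fit(bundles: Sequence[SiteBundle], k: int,
                fixed=None, random: Sequence[str] | None = None,
                site_effect: str | None = None
                ) -> dict[tuple[str, str], NormalizedQuantiles]:
    """Fit the step-1 quantile model on the pooled site summaries.

    Returns per-sample normalized quantiles keyed by (site, sample).  The
    result equals :func:`methylfn.normalize.fit_quantile_model` on the
    concatenated QC objects and is invariant to bundle order.  By default
    site identity is *not* a model covariate (the sites are normalized
    together); ``site_effect`` in {"fixed", "random"} adds it.
    """
    if not bundles:
        raise ValueError("central_fit needs at least one site bundle")
    keys: set[tuple[str, str]] = set()
    qcs: list[QCObject] = []
    key_of: dict[str, tuple[str, str]] = {}
    for b in bundles:
        for qc in b.qc_objects:
            key = (b.site_id, qc.sample_id)
            if key in keys:
                raise ValueError(f"duplicate (site, sample) key: {key}")
            if qc.sample_id in key_of:
                raise ValueError(
                    f"sample id {qc.sample_id!r} appears in sites "
                    f"{key_of[qc.sample_id][0]!r} and {b.site_id!r}; sample ids must be "
                    "globally unique for pooled-equivalent normalization"
                )
            keys.add(key)
            key_of[qc.sample_id] = key
            if site_effect:
                qc = QCObject.from_dict({**qc.to_dict(),
                                         "batch": {**qc.batch, "site": b.site_id}})
            qcs.append(qc)
    if len(qcs) < 3:
        raise ValueError("central_fit needs a combined n >= 3")
    if site_effect == "fixed":
        fixed = (list(fixed) if fixed else []) + ["site"]
    elif site_effect == "random":
        random = (list(random) if random else []) + ["site"]
    elif site_effect is not None:
        raise ValueError("site_effect must be None, 'fixed' or 'random'")

    _, targets = fit_quantile_model(qcs, k, fixed=fixed, random=random)
    return {key_of[t.sample_id]: t for t in targets}


def targets_to_json(targets: Mapping[tuple[str, str], NormalizedQuantiles]) -> str:
    payload = {"schema": _TARGETS_SCHEMA,
               "targets": [{"site_id": site, **t.to_dict()}
                           for (site, _sid), t in sorted(targets.items())]}
    return json.dumps(payload, sort_keys=True)


def targets_from_json(text: str) -> dict[tuple[str, str], NormalizedQuantiles]:
    d = json.loads(text)
    if d.get("schema") != _TARGETS_SCHEMA:
        raise ValueError(f"unexpected targets schema: {d.get('schema')!r}")
    out = {}
    for entry in d["targets"]:
        t = NormalizedQuantiles.from_dict({k: v for k, v in entry.items()
                                           if k != "site_id"})
        out[(entry["site_id"], t.sample_id)] = t
    return out


def finalize_site(dataset: RawDataset,
                  targets: Mapping[str, NormalizedQuantiles] | Mapping[tuple[str, str], NormalizedQuantiles],
                  offset: float = 100.0) -> pd.DataFrame:
    """Finalize every local sample from its returned targets.

    Accepts targets keyed by sample id or by (site, sample).  Targets for
    unknown samples are ignored with a warning; a missing target for a
    local sample is an error.  Betas are bit-identical to the pooled run.
    """
    by_sample: dict[str, NormalizedQuantiles] = {}
    for key, t in targets.items():
        sid = key[1] if isinstance(key, tuple) else key
        by_sample[sid] = t
    local = set(dataset.sample_ids)
    unknown = sorted(set(by_sample) - local)
    if unknown:
        warnings.warn(f"ignoring targets for unknown samples: {unknown}")
    missing = sorted(local - set(by_sample))
    if missing:
        raise ValueError(f"missing normalized-quantile targets for local samples: {missing}")

    cols = {}
    for s in dataset.samples:
        corrected = noob_correct(s, dataset.manifest)
        meth, unmeth = finalize_sample(corrected, by_sample[s.sample_id], dataset.manifest)
        cols[s.sample_id] = betas_for_sample(meth, unmeth, offset)
    return pd.DataFrame(cols)
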