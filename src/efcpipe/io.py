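"""Reading and writing cohort files, run configuration, and provenance.

All on-disk formats are plain text: per-subject T x R time-series TSVs with an
ROI-label header, a cohort manifest CSV (``subject_id, path, group``), an
ROI x network affiliation TSV, and JSON reports.  Every written bundle embeds
the resolved configuration and its hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CVConfig
from .errors import CohortFormatError, ParameterError
from .simulate import CohortTimeSeries, SimParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_cohort", "write_matrix_tsv", "config_hash"]


def read_cohort(manifest_path: str | Path) -> CohortTimeSeries:
    """Load a cohort from a manifest CSV; validates shapes and ROI ordering.

    The manifest needs columns ``subject_id``, ``path`` (TSV relative to the
    manifest or absolute), and ``group`` (+1/-1).  Every error names the
    offending subject.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "group"}
    missing = required - set(manifest.columns)
    if missing:
        raise CohortFormatError(f"manifest lacks columns: {sorted(missing)}")
    if manifest.empty:
        raise CohortFormatError("manifest lists no subjects")

    ids, mats, labels = [], [], []
    roi_labels: tuple[str, ...] | None = None
    T: int | None = None
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise CohortFormatError(f"subject {sid}: file not found: {path}")
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # malformed TSV
            raise CohortFormatError(f"subject {sid}: unreadable TSV ({exc})") from exc
        mat = df.to_numpy(dtype=float, na_value=np.nan)
        if np.isnan(mat).any():
            bad_row = int(np.argwhere(np.isnan(mat))[0, 0]) + 1
            raise CohortFormatError(
                f"subject {sid}: non-numeric or short row near data row {bad_row}"
            )
        cols = tuple(df.columns)
        if roi_labels is None:
            roi_labels, T = cols, mat.shape[0]
        else:
            if cols != roi_labels:
                raise CohortFormatError(
                    f"subject {sid}: ROI columns differ from first subject"
                )
            if mat.shape[0] != T:
                raise CohortFormatError(
                    f"subject {sid}: {mat.shape[0]} time points, expected {T}"
                )
        if (mat.std(axis=0) <= 1e-14).any():
            raise CohortFormatError(f"subject {sid}: zero-variance ROI column")
        lab = int(row.group)
        if lab not in (1, -1):
            raise CohortFormatError(f"subject {sid}: group must be +1 or -1, got {lab}")
        ids.append(sid)
        mats.append(mat)
        labels.append(lab)
    return CohortTimeSeries(
        tuple(ids), np.stack(mats), np.array(labels), roi_labels
    )


def write_matrix_tsv(mat: np.ndarray, path: str | Path, columns=None, index=None):
    """Write a matrix as TSV at full double precision (round-trip exact)."""
    df = pd.DataFrame(mat, columns=columns, index=index)
    df.to_csv(path, sep="\t", index=index is not None, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: simulation, CV protocol, attribution.

    Unknown keys in a YAML config are rejected; the resolved configuration is
    serialized into every output bundle.
    """

    sim: SimParams = field(default_factory=SimParams)
    cv: CVConfig = field(default_factory=CVConfig)
    affiliation_overlap: float = 0.2
    attribution_mode: str = "soft"  # "soft" | "hard"
    size_normalized: bool = False
    top_fraction: float = 0.05
    n_perm: int = 0
    run_baselines: bool = True
    outdir: str = "results/run"

    def validate(self) -> None:
        self.sim.validate()
        self.cv.validate()
        if self.attribution_mode not in ("soft", "hard"):
            raise ParameterError("attribution_mode must be 'soft' or 'hard'")
        if not (0 < self.top_fraction <= 1):
            raise ParameterError("top_fraction must be in (0, 1]")
        if self.n_perm < 0:
            raise ParameterError("n_perm must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            _check_keys(kwargs["sim"], SimParams, "sim")
            if "planted_edges" in kwargs["sim"] and kwargs["sim"]["planted_edges"]:
                kwargs["sim"]["planted_edges"] = tuple(
                    tuple(e) for e in kwargs["sim"]["planted_edges"]
                )
            kwargs["sim"] = SimParams(**kwargs["sim"])
        if "cv" in kwargs and isinstance(kwargs["cv"], dict):
            _check_keys(kwargs["cv"], CVConfig, "cv")
            for grid in ("window_grid", "cluster_grid"):
                if grid in kwargs["cv"]:
                    kwargs["cv"][grid] = tuple(kwargs["cv"][grid])
            kwargs["cv"] = CVConfig(**kwargs["cv"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)


def _check_keys(raw: dict, klass, name: str) -> None:
    known = {f.name for f in dataclasses.fields(klass)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown {name} config keys: {sorted(unknown)}")


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
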