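"""End-to-end pipeline runner: load -> epochs -> reconcile -> concordance
-> summarize -> associations, writing every derived artifact with a
content-hash manifest and JSON-lines stage logs."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import CategoryLabel, ValidationError
from .epochs import FollowupWindow
from .model import DEFAULT_ASSOCIATIONS, GCCStudy

__all__ = ["RunConfig", "run_pipeline", "load_resolutions"]


@dataclass
class RunConfig:
    patients_path: Union[str, Path]
    discussions_path: Union[str, Path]
    assessments_path: Union[str, Path]
    out_dir: Union[str, Path]
    resolutions_path: Optional[Union[str, Path]] = None
    window: FollowupWindow = field(default_factory=FollowupWindow)
    censor_at_ltfu: bool = False
    associations: Sequence[dict] = field(default_factory=lambda: list(DEFAULT_ASSOCIATIONS))
    make_plot: bool = True
    plot_format: str = "svg"
    quiet: bool = False


def load_resolutions(path: Union[str, Path]) -> dict:
    """Read a resolutions CSV: patient_id, epoch_index, consensus, adjudicator."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        key = (str(row["patient_id"]), int(row["epoch_index"]))
        out[key] = {
            "consensus": CategoryLabel.parse(row["consensus"]) if row.get("consensus") else None,
            "adjudicator": CategoryLabel.parse(row["adjudicator"]) if row.get("adjudicator") else None,
        }
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(quiet: bool, **payload) -> None:
    if not quiet:
        print(json.dumps(payload), file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    The manifest lists each written artifact with its SHA-256 content hash;
    a rerun on unchanged inputs reproduces identical hashes. A stage
    failure raises with the failing stage named; artifacts written by
    earlier stages are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "stages": []}
    t0 = time.time()

    def record(stage: str, **counts) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **counts}
        manifest["stages"].append(entry)
        _log(config.quiet, **entry)

    def write(name: str, df: pd.DataFrame) -> Path:
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest["artifacts"][name] = _sha256(path)
        return path

    stage = "load"
    try:
        resolutions = (load_resolutions(config.resolutions_path)
                       if config.resolutions_path else {})
        study = GCCStudy.from_files(
            config.patients_path, config.discussions_path, config.assessments_path,
            window=config.window, censor_at_ltfu=config.censor_at_ltfu,
            resolutions=resolutions,
        )
        record(stage, patients=study.bundle.n_patients,
               discussions=sum(len(v) for v in study.bundle.discussions.values()),
               assessments=len(study.bundle.all_assessments()))

        stage = "fit"
        res = study.fit(associations=config.associations)
        record("epochs", epochs=sum(len(v) for v in res.epochs_by_patient.values()))
        record("reconcile",
               final_calls=len(res.final_calls),
               disagreements_resolved=sum(
                   1 for c in res.final_calls if c.resolution.value != "agreement"))
        record("concordance", records=len(res.records))

        stage = "write"
        write("epochs.csv", res.epochs_frame())
        write("final_calls.csv", res.final_calls_frame())
        write("concordance.csv", res.records_frame())
        write("patient_summaries.csv", res.summaries_frame())
        if not res.associations.empty:
            write("associations.csv", res.associations)

        report = {
            "reliability": res.reliability.to_dict(),
            "reliability_by_confidence": {
                band: (r.to_dict() if r is not None else None)
                for band, r in res.reliability_by_confidence.items()
            },
            "cohort": res.cohort,
            "transitions": res.transitions,
            "uncertainty_breakdown": res.uncertainty_frame().to_dict("records"),
        }
        path = out_dir / "cohort_summary.json"
        path.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
        manifest["artifacts"]["cohort_summary.json"] = _sha256(path)

        if config.make_plot:
            stage = "plot"
            plot_path = out_dir / f"tile_plot.{config.plot_format}"
            res.tile_plot(out_path=plot_path)
            manifest["artifacts"][plot_path.name] = _sha256(plot_path)
        record("done", artifacts=len(manifest["artifacts"]))
    except Exception as exc:
        manifest["failed_stage"] = stage
        _log(config.quiet, stage=stage, error=str(exc))
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
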