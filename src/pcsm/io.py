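"""File formats: BIDS-style events, tab-separated matrices, JSON parameters.

Everything is plain text: events.tsv for trial tables, TSV with a header
row for matrices (with leading trial/delay index columns for FIR series and
posterior tables), JSON for model parameters, thresholds, reports and run
manifests.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .fir import FirSeries
from .simulator import GroundTruth
from .state_model import GmmHmmParams
from .thresholding import ThresholdSet

__all__ = [
    "write_events_tsv", "read_events_tsv",
    "write_fir_series", "read_fir_series",
    "write_ground_truth", "read_ground_truth",
    "write_params", "read_params",
    "write_thresholds", "read_thresholds",
    "write_manifest", "read_manifest",
    "read_bold_tsv",
]

_EVENT_COLS = ["onset", "duration", "trial_type", "response_time", "ssd", "outcome"]


def write_events_tsv(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as a BIDS-style events.tsv (n/a for missing)."""
    df = pd.DataFrame({
        "onset": trials["onset_s"],
        "duration": trials.get("duration_s", 0.0),
        "trial_type": trials["trial_type"],
        "response_time": np.where(trials["outcome"] == "stop_success",
                                  np.nan, trials["rt_s"]),
        "ssd": trials["ssd_s"],
        "outcome": trials["outcome"],
    })
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    out = pd.DataFrame({
        "trial_id": np.arange(len(df)),
        "onset_s": df["onset"].astype(float),
        "trial_type": df["trial_type"],
        "rt_s": df["response_time"] if "response_time" in df else np.nan,
        "ssd_s": df["ssd"] if "ssd" in df else np.nan,
        "outcome": df["outcome"] if "outcome" in df else "",
    })
    return out


def read_bold_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a timepoints x nodes BOLD table with node labels in the header."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_fir_series(fir: FirSeries, path: str | Path) -> None:
    fir.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_fir_series(path: str | Path, zscored: bool | None = None) -> FirSeries:
    df = pd.read_csv(path, sep="\t")
    nodes = [c for c in df.columns if c not in ("trial", "delay")]
    return FirSeries(values=df[nodes].to_numpy(dtype=float),
                     trials=df["trial"].to_numpy(dtype=int),
                     delays=df["delay"].to_numpy(dtype=int),
                     node_labels=nodes,
                     zscored=bool(zscored) if zscored is not None else False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame({"trial": truth.trials, "delay": truth.delays,
                  "state": truth.state_seq}).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path, regime: str = "",
                      noise_level: str = "") -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(state_seq=df["state"].to_numpy(dtype=int),
                       trials=df["trial"].to_numpy(dtype=int),
                       delays=df["delay"].to_numpy(dtype=int),
                       regime=regime, noise_level=noise_level)


def write_params(params: GmmHmmParams, path: str | Path) -> None:
    payload = {
        "C": params.C, "M": params.M, "N": params.N,
        "responding_mixture_index": params.responding_mixture_index,
        "startprob": params.startprob.tolist(),
        "transmat": params.transmat.tolist(),
        "weights": params.weights.tolist(),
        "means": params.means.tolist(),
        "variances": params.variances.tolist(),
        "spatial_cov": None if params.spatial_cov is None
        else params.spatial_cov.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_params(path: str | Path) -> GmmHmmParams:
    d = json.loads(Path(path).read_text())
    return GmmHmmParams(
        startprob=np.asarray(d["startprob"]), transmat=np.asarray(d["transmat"]),
        weights=np.asarray(d["weights"]), means=np.asarray(d["means"]),
        variances=np.asarray(d["variances"]),
        spatial_cov=None if d.get("spatial_cov") is None
        else np.asarray(d["spatial_cov"]),
        responding_mixture_index=int(d.get("responding_mixture_index", 1)))


def write_thresholds(thresholds: dict[str, ThresholdSet], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.to_dict() for k, v in thresholds.items()}, indent=2, default=float))


def read_thresholds(path: str | Path) -> dict[str, ThresholdSet]:
    raw = json.loads(Path(path).read_text())
    return {k: ThresholdSet(metric=v.get("metric", k), taus=v["taus"],
                            method=v["method"],
                            separation_d=v.get("separation_d"),
                            mixture_summary=v.get("mixture_summary"),
                            ci=v.get("ci"), sensitivity=v.get("sensitivity"),
                            extras=v.get("extras", {}))
            for k, v in raw.items()}


def write_manifest(path: str | Path, command: str, seed: int | None,
                   config: dict, stages: dict | None = None,
                   inputs: dict | None = None, outputs: dict | None = None) -> None:
    from . import __version__
    payload = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": inputs or {},
        "outputs": outputs or {},
        "stages": stages or {},
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
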