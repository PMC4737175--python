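"""File formats: trace CSVs with JSON truth sidecars, profile TSVs,
time-course CSVs.

A trace is stored as a three-column CSV (scan, reporter, standard) next to
a ``<name>.meta.json`` sidecar holding the metadata, seed and — for
simulated traces — the true yield profile, so round-trip analyses can be
scored against the truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import TimeCourse
from .simulate import Electropherogram, TrueYieldProfile


def write_trace(trace: Electropherogram, path, profile: TrueYieldProfile | None = None):
    path = Path(path)
    df = pd.DataFrame(
        {"scan": trace.scan, "reporter": trace.reporter, "standard": trace.standard}
    )
    df.to_csv(path, index=False, float_format="%.4f")
    sidecar = {"metadata": trace.metadata}
    if profile is not None:
        sidecar["true_profile"] = {
            "pool": profile.pool,
            "product_fraction": {
                f"{u}/p{d}": v for (u, d), v in profile.product_fraction.items()
            },
            "adenylylated_fraction": dict(profile.adenylylated_fraction),
        }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_trace(path) -> Electropherogram:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    metadata = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text()).get("metadata", {})
    return Electropherogram(
        scan=df["scan"].to_numpy(float),
        reporter=df["reporter"].to_numpy(float),
        standard=df["standard"].to_numpy(float),
        metadata=metadata,
    )


def read_true_profile(trace_path) -> TrueYieldProfile | None:
    meta_path = Path(trace_path).with_suffix(".meta.json")
    if not meta_path.exists():
        return None
    doc = json.loads(meta_path.read_text()).get("true_profile")
    if doc is None:
        return None
    products = {}
    for key, v in doc["product_fraction"].items():
        u, d = key.split("/p")
        products[(u, d)] = v
    return TrueYieldProfile(doc["pool"], products, doc["adenylylated_fraction"])


def write_profiles_tsv(profiles: Mapping[str, TrueYieldProfile], path):
    rows = []
    for pool, prof in profiles.items():
        for (u, d), v in sorted(prof.product_fraction.items()):
            rows.append((pool, u, d, v))
        for d, v in sorted(prof.adenylylated_fraction.items()):
            if v > 0:
                rows.append((pool, "App", d, v))
    pd.DataFrame(rows, columns=["pool", "up", "down", "fraction"]).to_csv(
        path, sep="\t", index=False
    )


def write_timecourse(tc: TimeCourse, path):
    pd.DataFrame(
        {"time_s": tc.times, "fraction": tc.fraction, "replicate": tc.replicate}
    ).to_csv(path, index=False)


def read_timecourses(path, substrate_conc: float) -> list[TimeCourse]:
    """Read one or more replicates from a time-course CSV.

    Expected columns: time_s, fraction, optional replicate.
    """
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = "r1"
    out = []
    for rep, sub in df.groupby("replicate", sort=False):
        sub = sub.sort_values("time_s")
        out.append(
            TimeCourse(
                times=sub["time_s"].to_numpy(float),
                fraction=np.clip(sub["fraction"].to_numpy(float), 0.0, 1.0),
                substrate_conc=substrate_conc,
                replicate=str(rep),
            )
        )
    return out
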