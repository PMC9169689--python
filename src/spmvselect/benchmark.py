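"""SpMV timing harness, GFLOPs metric and labelled benchmark datasets.

A benchmark record ties a matrix's feature vector to the measured SpMV
throughput of each candidate layout and to the label ``best_format`` —
the layout with the highest throughput.  Throughput uses the standard
SpMV accounting of one multiply plus one add per stored nonzero:

    GFLOPs = 2 * steps * nnz / t / 1e9

with ``t`` the wall time of ``steps`` consecutive products.  Timing
excludes format conversion and memory setup; each layout gets one
discarded warm-up pass, and the timed trials are aggregated with the
median by default (robust to scheduler noise; the mean is available).
Before any timing, every kernel's output is cross-checked against the
brute-force dense product — measuring a wrong kernel is meaningless.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .connectivity import GeneratorConfig, sample_configuration
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .formats import ConnectivityMatrix, convert

__all__ = [
    "FORMAT_PRIORITY",
    "gflops_metric",
    "best_format_of",
    "BenchmarkRecord",
    "Dataset",
    "benchmark_matrix",
    "build_dataset",
]

#: Candidate formats benchmarked by default, which is also the tie-break
#: priority for ``best_format`` (CSR is most often optimal in practice).
FORMAT_PRIORITY = ("csr", "ellpack_r", "dense")

#: Short column suffixes used in the dataset CSV schema.
_CSV_SUFFIX = {"csr": "csr", "ellpack_r": "ellr", "dense": "dense"}
_CSV_COLUMNS = (
    ("sample_id",) + FEATURE_NAMES
    + tuple(f"time_{_CSV_SUFFIX[f]}" for f in FORMAT_PRIORITY)
    + tuple(f"gflops_{_CSV_SUFFIX[f]}" for f in FORMAT_PRIORITY)
    + ("best_format",)
)


def gflops_metric(t: float, nnz: int, steps: int = 1000) -> float:
    """Throughput of ``steps`` SpMV products over ``nnz`` nonzeros in ``t`` s."""
    if t <= 0:
        raise ValueError(f"measured time must be positive, got {t}")
    if nnz < 0:
        raise ValueError("nnz must be nonnegative")
    return 2.0 * steps * nnz / t / 1e9


def best_format_of(gflops: Mapping[str, float],
                   priority: Sequence[str] = FORMAT_PRIORITY) -> str:
    """Argmax over per-format throughput; exact ties follow ``priority``."""
    best = max(gflops.values())
    for name in priority:
        if name in gflops and gflops[name] == best:
            return name
    # formats outside the priority list: fall back to dict order
    return max(gflops, key=gflops.__getitem__)


@dataclass(frozen=True)
class BenchmarkRecord:
    features: FeatureVector
    gflops: Dict[str, float]
    time_s: Dict[str, float]
    best_format: str
    sample_id: int = 0
    raw_times: Dict[str, tuple] = field(default_factory=dict, repr=False)
    true_best: Optional[str] = None  # noiseless label, simulated devices only

    def to_csv_row(self) -> dict:
        f = self.features
        row = {"sample_id": self.sample_id}
        row.update(dict(zip(FEATURE_NAMES, f.as_array().tolist())))
        row["nnz"] = f.nnz
        row["n"], row["m"] = f.n, f.m
        row["minnzr"], row["maxnzr"] = f.minnzr, f.maxnzr
        for fmt in FORMAT_PRIORITY:
            row[f"time_{_CSV_SUFFIX[fmt]}"] = self.time_s[fmt]
            row[f"gflops_{_CSV_SUFFIX[fmt]}"] = self.gflops[fmt]
        row["best_format"] = self.best_format
        return row

    @classmethod
    def from_csv_row(cls, row: Mapping) -> "BenchmarkRecord":
        f = FeatureVector(
            n=int(row["n"]), m=int(row["m"]), nnz=int(row["nnz"]),
            des=float(row["des"]), avgnzr=float(row["avgnzr"]),
            minnzr=int(row["minnzr"]), maxnzr=int(row["maxnzr"]),
        )
        gflops = {fmt: float(row[f"gflops_{_CSV_SUFFIX[fmt]}"])
                  for fmt in FORMAT_PRIORITY}
        time_s = {fmt: float(row[f"time_{_CSV_SUFFIX[fmt]}"])
                  for fmt in FORMAT_PRIORITY}
        return cls(
            features=f, gflops=gflops, time_s=time_s,
            best_format=str(row["best_format"]),
            sample_id=int(row["sample_id"]),
        )


@dataclass
class Dataset:
    """A sequence of benchmark records plus provenance metadata."""

    records: List[BenchmarkRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    # -- matrix views used by the predictor ---------------------------
    def feature_matrix(self) -> np.ndarray:
        return np.stack([r.features.as_array() for r in self.records])

    def target_matrix(self) -> np.ndarray:
        """Per-format GFLOPs targets in FORMAT_PRIORITY column order."""
        return np.array(
            [[r.gflops[fmt] for fmt in FORMAT_PRIORITY] for r in self.records]
        )

    def labels(self) -> np.ndarray:
        return np.array([r.best_format for r in self.records])

    # -- CSV + JSON-sidecar serialization -----------------------------
    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        pd.DataFrame([r.to_csv_row() for r in self.records],
                     columns=_CSV_COLUMNS).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        records = [BenchmarkRecord.from_csv_row(row) for _, row in df.iterrows()]
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(records=records, provenance=provenance)


def _aggregate(times: Sequence[float], how: str) -> float:
    if how == "median":
        return float(np.median(times))
    if how == "mean":
        return float(np.mean(times))
    raise ValueError(f"unknown aggregation {how!r}")


def benchmark_matrix(
    m: ConnectivityMatrix,
    steps: int = 1000,
    repetitions: int = 5,
    rng: Optional[np.random.Generator] = None,
    formats: Sequence[str] = FORMAT_PRIORITY,
    aggregate: str = "median",
    sample_id: int = 0,
) -> BenchmarkRecord:
    """Time ``steps`` SpMV products per layout and label the fastest.

    Conversion happens before the clock starts.  Each repetition times a
    fresh U(0,1) input vector (content does not affect the arithmetic cost
    but prevents degenerate constant folding); per-format wall times are
    aggregated across repetitions and converted to GFLOPs.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = rng or np.random.default_rng()
    feats = extract_features(m)

    mats = {name: convert(m, name) for name in formats}

    # correctness gate: every kernel must agree with the dense brute force
    x0 = rng.random(m.n_cols)
    reference = m.to_dense() @ x0
    scale = np.maximum(np.abs(reference), 1.0)
    for name, fm in mats.items():
        err = np.max(np.abs(fm.spmv(x0) - reference) / scale)
        if not err <= 1e-10:
            raise RuntimeError(
                f"{name} SpMV disagrees with the dense oracle "
                f"(max relative error {err:.3e}); refusing to time it"
            )

    raw: Dict[str, List[float]] = {name: [] for name in formats}
    for name, fm in mats.items():
        fm.spmv(x0)  # warm-up, discarded
        for _ in range(repetitions):
            x = rng.random(m.n_cols)
            t0 = time.perf_counter()
            for _ in range(steps):
                fm.spmv(x)
            raw[name].append(time.perf_counter() - t0)

    time_s = {name: _aggregate(raw[name], aggregate) for name in formats}
    gflops = {name: gflops_metric(time_s[name], feats.nnz, steps)
              for name in formats}
    return BenchmarkRecord(
        features=feats,
        gflops=gflops,
        time_s=time_s,
        best_format=best_format_of(gflops),
        sample_id=sample_id,
        raw_times={name: tuple(raw[name]) for name in formats},
    )


def build_dataset(
    cfg: GeneratorConfig,
    n_samples: int,
    steps: int = 1000,
    repetitions: int = 5,
    rng: Optional[np.random.Generator] = None,
    csv_path: Optional[Union[str, Path]] = None,
    aggregate: str = "median",
    progress: Optional[Callable[[int, BenchmarkRecord], None]] = None,
) -> Dataset:
    """Generate, benchmark and label ``n_samples`` random configurations.

    When ``csv_path`` is given, each record is appended to the CSV as soon
    as it is measured, so a partial run is recoverable.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng or np.random.default_rng()
    provenance = {
        "device": "cpu-reference",
        "steps": steps,
        "repetitions": repetitions,
        "aggregate": aggregate,
        "generator_config": dataclasses.asdict(cfg),
        "timing_reproducible": False,
    }

    path = Path(csv_path) if csv_path is not None else None
    handle = None
    if path is not None:
        handle = path.open("w")
        handle.write(",".join(_CSV_COLUMNS) + "\n")
        handle.flush()

    records: List[BenchmarkRecord] = []
    try:
        for i in range(n_samples):
            try:
                m = sample_configuration(cfg, rng)
                rec = benchmark_matrix(
                    m, steps=steps, repetitions=repetitions, rng=rng,
                    aggregate=aggregate, sample_id=i,
                )
            except Exception as exc:
                raise RuntimeError(f"benchmark failed at sample {i}: {exc}") from exc
            records.append(rec)
            if handle is not None:
                row = rec.to_csv_row()
                handle.write(",".join(str(row[c]) for c in _CSV_COLUMNS) + "\n")
                handle.flush()
            if progress is not None:
                progress(i, rec)
    finally:
        if handle is not None:
            handle.close()

    ds = Dataset(records=records, provenance=provenance)
    if path is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=str))
    return ds
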