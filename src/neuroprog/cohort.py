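"""Longitudinal multimodal cohort data model and file I/O.

This module is the single source of truth for coordinate and unit conventions
in the package:

* time is measured in **years from each subject's baseline visit**; the
  baseline visit is exactly ``t = 0`` and all visit times are nonnegative;
* ordinal disease stages form the vocabulary ``{0, ..., L}``;
* per-subject visits are kept sorted by time and strictly increasing;
* missing cognitive scores, stage labels and biomarker vectors are stored as
  explicit missing values (``None`` / NaN) and masked out of every loss
  downstream — nothing is imputed here;
* the brain-region graph is directed; the neighbourhood ``N(v)`` used by all
  propagation and simulation code is the set of **in-neighbours** of ``v``.
  An undirected edge list is read as both directions.

On disk a cohort is four plain-text files: ``baseline.csv`` (one row per
subject: imaging / omics / demographic feature blocks), ``visits.csv`` (one
row per visit: time, cognitive score, optional stage, optional biomarker
vector; empty cells are missing), ``treatments.csv`` (treatment code and
onset time per treated subject) and ``graph.json`` (region ids, weighted
directed edges and the symmetric compatibility kernel).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModalityBlock",
    "ObservationRecord",
    "TreatmentEvent",
    "Subject",
    "RegionGraph",
    "Cohort",
    "CohortFormatError",
    "load_cohort",
    "save_cohort",
    "validate_cohort",
    "split_cohort",
]


class CohortFormatError(ValueError):
    """A cohort file violates the column schema or a type invariant."""


@dataclass
class ModalityBlock:
    """Per-subject baseline feature blocks, one vector per modality."""

    imaging: np.ndarray
    omics: np.ndarray
    demographics: np.ndarray

    @property
    def full(self) -> np.ndarray:
        """Concatenation of the three blocks (the baseline feature vector)."""
        return np.concatenate([self.imaging, self.omics, self.demographics])


@dataclass
class ObservationRecord:
    """One timed visit: cognitive score, optional stage, optional biomarkers."""

    subject_id: str
    time: float
    cognitive_score: Optional[float] = None
    stage_label: Optional[int] = None
    biomarkers: Optional[np.ndarray] = None


@dataclass
class TreatmentEvent:
    subject_id: str
    treatment_code: str
    onset_time: float
    post_outcomes: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Subject:
    subject_id: str
    baseline: ModalityBlock
    visits: list[ObservationRecord]
    treatments: list[TreatmentEvent] = field(default_factory=list)


@dataclass
class RegionGraph:
    """Directed weighted region graph with a symmetric compatibility kernel."""

    region_ids: list[str]
    edges: list[tuple[str, str, float]]
    kernel: np.ndarray

    def index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def in_neighbors(self, region_id: str) -> list[str]:
        """N(v): sources of edges pointing into `region_id`."""
        return [src for src, dst, _ in self.edges if dst == region_id]

    def adjacency(self) -> np.ndarray:
        """Weight matrix A with A[u, v] = weight of edge u -> v."""
        n = self.n_regions
        idx = {r: i for i, r in enumerate(self.region_ids)}
        a = np.zeros((n, n))
        for src, dst, w in self.edges:
            a[idx[src], idx[dst]] = w
        return a


@dataclass
class Cohort:
    subjects: dict[str, Subject]
    stage_count: int  # L + 1
    region_graph: Optional[RegionGraph] = None
    time_horizon: float = 0.0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def all_visits(self):
        for sid in self.subjects:
            yield from self.subjects[sid].visits


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _block_columns(columns: Sequence[str], prefix: str) -> list[str]:
    cols = [c for c in columns if c.startswith(prefix)]
    cols.sort(key=lambda c: int(c[len(prefix):]))
    for i, c in enumerate(cols):
        if int(c[len(prefix):]) != i:
            raise CohortFormatError(
                f"column block '{prefix}*' is not contiguous 0-based: found {cols}"
            )
    return cols


def load_cohort(
    baseline_path,
    visits_path,
    treatments_path=None,
    graph_path=None,
    stage_count: Optional[int] = None,
) -> Cohort:
    """Read a cohort from its CSV/JSON files and validate it.

    Parameters
    ----------
    baseline_path, visits_path
        Required CSV files (``subject_id, img_*, omics_*, demo_*`` and
        ``subject_id, time, cognitive_score, stage, bio_*``).
    treatments_path, graph_path
        Optional treatment-event CSV and region-graph JSON.
    stage_count
        Size of the stage vocabulary (L+1). If ``None`` it is inferred as
        ``max observed stage + 1``.

    Raises
    ------
    CohortFormatError
        Naming file, row and column for schema violations, negative times,
        out-of-vocabulary stages or duplicated (subject, time) pairs.
    """
    baseline = pd.read_csv(baseline_path, dtype={"subject_id": str})
    visits = pd.read_csv(visits_path, dtype={"subject_id": str})
    if "subject_id" not in baseline.columns:
        raise CohortFormatError(f"{baseline_path}: missing column 'subject_id'")
    for col in ("subject_id", "time"):
        if col not in visits.columns:
            raise CohortFormatError(f"{visits_path}: missing column '{col}'")

    img_cols = _block_columns(baseline.columns, "img_")
    omics_cols = _block_columns(baseline.columns, "omics_")
    demo_cols = _block_columns(baseline.columns, "demo_")
    bio_cols = _block_columns(visits.columns, "bio_")

    subjects: dict[str, Subject] = {}
    for row_i, row in baseline.iterrows():
        sid = str(row["subject_id"])
        if sid in subjects:
            raise CohortFormatError(
                f"{baseline_path}: row {row_i}: duplicate subject_id '{sid}'"
            )
        block = ModalityBlock(
            imaging=row[img_cols].to_numpy(dtype=float),
            omics=row[omics_cols].to_numpy(dtype=float),
            demographics=row[demo_cols].to_numpy(dtype=float),
        )
        if not np.all(np.isfinite(block.full)):
            raise CohortFormatError(
                f"{baseline_path}: row {row_i}: non-finite baseline feature"
            )
        subjects[sid] = Subject(sid, block, visits=[])

    seen_times: dict[str, set] = {sid: set() for sid in subjects}
    max_stage = -1
    horizon = 0.0
    for row_i, row in visits.iterrows():
        sid = str(row["subject_id"])
        if sid not in subjects:
            raise CohortFormatError(
                f"{visits_path}: row {row_i}: unknown subject_id '{sid}'"
            )
        t = float(row["time"])
        if not math.isfinite(t) or t < 0:
            raise CohortFormatError(
                f"{visits_path}: row {row_i}, column 'time': "
                f"time must be a finite nonnegative number, got {row['time']}"
            )
        if t in seen_times[sid]:
            raise CohortFormatError(
                f"{visits_path}: row {row_i}: duplicate visit time {t} "
                f"for subject '{sid}'"
            )
        seen_times[sid].add(t)
        horizon = max(horizon, t)

        score = row.get("cognitive_score", np.nan)
        score = None if pd.isna(score) else float(score)
        stage = row.get("stage", np.nan)
        if pd.isna(stage):
            stage = None
        else:
            stage = int(stage)
            if stage < 0:
                raise CohortFormatError(
                    f"{visits_path}: row {row_i}, column 'stage': "
                    f"negative stage {stage}"
                )
            max_stage = max(max_stage, stage)
        bio = None
        if bio_cols:
            vals = row[bio_cols].to_numpy(dtype=float)
            bio = None if np.all(np.isnan(vals)) else vals
        subjects[sid].visits.append(
            ObservationRecord(sid, t, score, stage, bio)
        )

    for subj in subjects.values():
        subj.visits.sort(key=lambda v: v.time)

    if stage_count is None:
        stage_count = max(max_stage + 1, 1)
    elif max_stage >= stage_count:
        raise CohortFormatError(
            f"{visits_path}: stage label {max_stage} outside vocabulary "
            f"{{0..{stage_count - 1}}}"
        )

    if treatments_path is not None and Path(treatments_path).exists():
        tdf = pd.read_csv(treatments_path, dtype={"subject_id": str,
                                                  "treatment_code": str})
        for row_i, row in tdf.iterrows():
            sid = str(row["subject_id"])
            if sid not in subjects:
                raise CohortFormatError(
                    f"{treatments_path}: row {row_i}: unknown subject '{sid}'"
                )
            onset = float(row["onset_time"])
            if onset < 0:
                raise CohortFormatError(
                    f"{treatments_path}: row {row_i}: negative onset_time"
                )
            ev = TreatmentEvent(sid, str(row["treatment_code"]), onset)
            # post-onset observed outcomes come from the visit table
            ev.post_outcomes = [
                (v.time, v.cognitive_score)
                for v in subjects[sid].visits
                if v.time >= onset and v.cognitive_score is not None
            ]
            subjects[sid].treatments.append(ev)

    graph = None
    if graph_path is not None and Path(graph_path).exists():
        graph = load_region_graph(graph_path)

    cohort = Cohort(subjects, stage_count, graph, horizon)
    report = validate_cohort(cohort)
    if report:
        raise CohortFormatError("; ".join(report))
    return cohort


def load_region_graph(graph_path) -> RegionGraph:
    with open(graph_path) as fh:
        spec = json.load(fh)
    kernel = np.asarray(spec["kernel"], dtype=float)
    return RegionGraph(
        region_ids=[str(r) for r in spec["region_ids"]],
        edges=[(str(s), str(d), float(w)) for s, d, w in spec["edges"]],
        kernel=kernel,
    )


def save_cohort(cohort: Cohort, out_dir) -> None:
    """Write baseline.csv, visits.csv, treatments.csv and graph.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for sid, subj in cohort.subjects.items():
        row = {"subject_id": sid}
        for i, v in enumerate(subj.baseline.imaging):
            row[f"img_{i}"] = v
        for i, v in enumerate(subj.baseline.omics):
            row[f"omics_{i}"] = v
        for i, v in enumerate(subj.baseline.demographics):
            row[f"demo_{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "baseline.csv", index=False)

    vrows = []
    for visit in cohort.all_visits():
        row = {
            "subject_id": visit.subject_id,
            "time": visit.time,
            "cognitive_score": visit.cognitive_score,
            "stage": visit.stage_label,
        }
        if visit.biomarkers is not None:
            for i, v in enumerate(visit.biomarkers):
                row[f"bio_{i}"] = v
        vrows.append(row)
    pd.DataFrame(vrows).to_csv(out / "visits.csv", index=False)

    trows = [
        {"subject_id": ev.subject_id, "treatment_code": ev.treatment_code,
         "onset_time": ev.onset_time}
        for subj in cohort.subjects.values()
        for ev in subj.treatments
    ]
    pd.DataFrame(trows, columns=["subject_id", "treatment_code",
                                 "onset_time"]).to_csv(
        out / "treatments.csv", index=False
    )

    if cohort.region_graph is not None:
        g = cohort.region_graph
        with open(out / "graph.json", "w") as fh:
            json.dump(
                {
                    "region_ids": g.region_ids,
                    "edges": [[s, d, w] for s, d, w in g.edges],
                    "kernel": g.kernel.tolist(),
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Validation & splitting
# ---------------------------------------------------------------------------

def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every type invariant; return a report of violations (empty = ok).

    Reporting, not raising: entries name the subject and field concerned.
    """
    report: list[str] = []
    for sid, subj in cohort.subjects.items():
        if not np.all(np.isfinite(subj.baseline.full)):
            report.append(f"subject {sid}: baseline features contain non-finite values")
        times = [v.time for v in subj.visits]
        if any(t < 0 for t in times):
            report.append(f"subject {sid}: visit time < 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            report.append(f"subject {sid}: visits not strictly increasing in time")
        for v in subj.visits:
            if v.stage_label is not None and not (
                0 <= v.stage_label < cohort.stage_count
            ):
                report.append(
                    f"subject {sid}: stage_label {v.stage_label} outside "
                    f"{{0..{cohort.stage_count - 1}}}"
                )
            if v.biomarkers is not None and not np.all(
                np.isfinite(v.biomarkers) | np.isnan(v.biomarkers)
            ):
                report.append(f"subject {sid}: biomarker vector has infinities")
        for ev in subj.treatments:
            if any(t < ev.onset_time for t, _ in ev.post_outcomes):
                report.append(
                    f"subject {sid}: treatment '{ev.treatment_code}' has "
                    f"post-outcome before onset"
                )
    g = cohort.region_graph
    if g is not None:
        if g.kernel.shape != (g.n_regions, g.n_regions):
            report.append("region_graph: kernel shape does not match region count")
        else:
            if not np.allclose(g.kernel, g.kernel.T):
                report.append("region_graph: compatibility kernel not symmetric")
            if np.any(g.kernel < 0):
                report.append("region_graph: compatibility kernel has negative entries")
        if any(s == d for s, d, _ in g.edges):
            report.append("region_graph: self-loop in edge list")
    return report


def split_cohort(
    cohort: Cohort, fractions: tuple[float, float, float], seed: int
) -> tuple[Cohort, Cohort, Cohort]:
    """Subject-level train/validation/test split (no subject straddles splits).

    Same seed gives the identical split. Fractions must be positive and sum
    to 1; split sizes are largest-remainder rounded so they sum to the cohort
    size.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be three positive numbers, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {sum(fractions)}")

    ids = sorted(cohort.subjects)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    raw = [f * n for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1

    parts = []
    offset = 0
    for size in sizes:
        member_ids = ids[offset: offset + size]
        offset += size
        parts.append(
            Cohort(
                subjects={sid: cohort.subjects[sid] for sid in member_ids},
                stage_count=cohort.stage_count,
                region_graph=cohort.region_graph,
                time_horizon=cohort.time_horizon,
            )
        )
    return tuple(parts)
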