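"""Cohort data model, exclusion filters, cumulative-average intake and file I/O.

The cohort is a :class:`pandas.DataFrame` indexed by participant id with one
row per participant (covariates, incident-outcome flag, person-years).
Per-visit food-group intakes live in an :class:`IntakeMatrix`. All readers
and writers use plain delimited text so that artifacts diff and round-trip
cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError

#: covariates whose absence excludes a participant ("missing key covariates")
KEY_COVARIATES = ("education_high", "exercise_regular", "smoking", "alcohol", "bmi")

#: full cohort schema (beyond the participant-id index)
COHORT_COLUMNS = (
    "sex",
    "age",
    "education_high",
    "exercise_regular",
    "smoking",
    "alcohol",
    "bmi",
    "fbg_baseline",
    "on_antidiabetic_meds",
    "person_years",
    "incident_t2d",
    "diagnosis_visit",
)

SMOKING_LEVELS = ("never", "former", "current")
SEX_LEVELS = ("male", "female")


@dataclass
class IntakeMatrix:
    """Per-visit food-group intakes (servings/day) and energy (kcal/day).

    ``frames[v]`` is a participants × foods DataFrame for visit ``v``;
    ``energy[v]`` the matching per-participant energy Series. Visits are
    integer-keyed and ordered; the smallest key is the baseline visit.
    """

    frames: dict[int, pd.DataFrame]
    energy: dict[int, pd.Series]

    def __post_init__(self) -> None:
        if not self.frames:
            raise DataError("IntakeMatrix needs at least one visit")
        foods = self.foods
        if len(set(foods)) != len(foods):
            dupes = sorted({f for f in foods if list(foods).count(f) > 1})
            raise DataError(f"duplicate food-group names: {dupes}")
        for v, frame in self.frames.items():
            if (frame.to_numpy() < 0).any():
                bad = frame.lt(0).any()
                raise DataError(
                    f"negative intake at visit {v} for foods "
                    f"{sorted(bad[bad].index)}"
                )
            if list(frame.columns) != list(foods):
                raise DataError(f"visit {v} has a different food set")

    @property
    def visits(self) -> list[int]:
        return sorted(self.frames)

    @property
    def baseline_visit(self) -> int:
        return min(self.frames)

    @property
    def foods(self) -> list[str]:
        return list(self.frames[min(self.frames)].columns)

    @property
    def participants(self) -> pd.Index:
        return self.frames[self.baseline_visit].index

    def restrict(self, ids: Iterable) -> "IntakeMatrix":
        """Sub-matrix for the given participants (visits they attended)."""
        ids = pd.Index(ids)
        frames = {}
        energy = {}
        for v in self.visits:
            keep = self.frames[v].index.intersection(ids)
            frames[v] = self.frames[v].loc[keep]
            energy[v] = self.energy[v].loc[keep]
        return IntakeMatrix(frames, energy)


@dataclass
class CumulativeIntake:
    """Per-participant cumulative-average intakes and energy."""

    intake: pd.DataFrame  # participants × foods, servings/day
    energy: pd.Series  # kcal/day

    @property
    def foods(self) -> list[str]:
        return list(self.intake.columns)


@dataclass
class ExclusionLog:
    """One reason per removed participant, plus the thresholds applied.

    Reasons are assigned in fixed order (first matching rule):
    antidiabetic medication / high fasting glucose -> ``prevalent_diabetes``,
    missing baseline energy -> ``missing_dietary``, energy at or beyond the
    percentile band -> ``energy_outlier``, then ``missing_covariate``.
    """

    reasons: dict = field(default_factory=dict)
    energy_bounds: tuple[float, float] | None = None
    n_input: int = 0
    n_retained: int = 0

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reasons.values():
            out[r] = out.get(r, 0) + 1
        return out

    def to_json(self, path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "energy_bounds": list(self.energy_bounds) if self.energy_bounds else None,
            "counts": self.counts(),
            "reasons": {str(k): v for k, v in self.reasons.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Schema and invariant checks; raises :class:`DataError` on violation."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DataError(f"cohort table missing columns: {missing}")
    if cohort.index.has_duplicates:
        dupes = cohort.index[cohort.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate participant id(s): {dupes}")
    if (cohort["person_years"] <= 0).any():
        bad = cohort.index[cohort["person_years"] <= 0].tolist()
        raise DataError(f"non-positive person_years for participants {bad}")
    flag = cohort["incident_t2d"].astype(bool)
    has_dx = cohort["diagnosis_visit"].notna()
    if (flag != has_dx).any():
        bad = cohort.index[flag != has_dx].tolist()
        raise DataError(
            f"diagnosis_visit must be present iff incident_t2d; offenders {bad}"
        )


def apply_exclusions(
    cohort: pd.DataFrame,
    intake: IntakeMatrix,
    energy_low_pct: float = 0.005,
    energy_high_pct: float = 0.995,
    energy_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the prevalent-disease / dietary / covariate exclusion cascade.

    Prevalent diabetes means anti-diabetic medication use or fasting blood
    glucose >= 126 mg/dL at baseline. Energy trimming removes participants
    whose baseline energy lies at or beyond the ``energy_low_pct`` /
    ``energy_high_pct`` percentiles (linear-interpolation estimator) of
    baseline energy within the input cohort. ``energy_bounds`` overrides the
    percentile computation with explicit (low, high) kcal values, e.g. the
    bounds recorded in a previous :class:`ExclusionLog`; with fixed bounds
    the operation is idempotent.
    """
    log = ExclusionLog(n_input=len(cohort))
    base_energy = intake.energy[intake.baseline_visit].reindex(cohort.index)
    if energy_bounds is None:
        observed = base_energy.dropna()
        if observed.empty:
            raise DataError("no baseline energy values to compute percentiles")
        lo = float(np.quantile(observed.to_numpy(), energy_low_pct))
        hi = float(np.quantile(observed.to_numpy(), energy_high_pct))
    else:
        lo, hi = map(float, energy_bounds)
    log.energy_bounds = (lo, hi)

    prevalent = cohort["on_antidiabetic_meds"].fillna(False).astype(bool) | (
        cohort["fbg_baseline"] >= 126.0
    )
    missing_diet = base_energy.isna()
    energy_out = (base_energy <= lo) | (base_energy >= hi)
    missing_cov = cohort[list(KEY_COVARIATES)].isna().any(axis=1)

    for pid in cohort.index:
        if prevalent.loc[pid]:
            log.reasons[pid] = "prevalent_diabetes"
        elif missing_diet.loc[pid]:
            log.reasons[pid] = "missing_dietary"
        elif energy_out.loc[pid]:
            log.reasons[pid] = "energy_outlier"
        elif missing_cov.loc[pid]:
            log.reasons[pid] = "missing_covariate"
    kept = cohort.loc[~cohort.index.isin(log.reasons)]
    log.n_retained = len(kept)
    if kept.empty:
        raise DataError("all participants excluded; check exclusion thresholds")
    return kept, log


def cumulative_average(
    intake: IntakeMatrix,
    cohort: pd.DataFrame,
    design: str = "multi_visit",
) -> CumulativeIntake:
    """Average repeated dietary assessments taken before diagnosis/censoring.

    ``multi_visit``: per participant, the mean over all attended visits with
    visit index strictly before ``diagnosis_visit`` (all attended visits when
    there is no diagnosis). ``baseline_plus_one``: two dietary assessments
    (baseline and one follow-up); baseline only if the diagnosis precedes the
    follow-up assessment, else the mean of both.
    """
    if design not in ("multi_visit", "baseline_plus_one"):
        raise DataError(f"unknown design {design!r}")
    visits = intake.visits
    baseline = intake.baseline_visit
    followup = visits[1] if len(visits) > 1 else None

    rows = []
    energies = []
    ids = []
    for pid in cohort.index:
        dx = cohort.at[pid, "diagnosis_visit"]
        dx = None if pd.isna(dx) else int(dx)
        if design == "multi_visit":
            eligible = [
                v
                for v in visits
                if pid in intake.frames[v].index and (dx is None or v < dx)
            ]
        else:
            if followup is None or dx is not None and dx <= followup:
                eligible = [baseline] if pid in intake.frames[baseline].index else []
            else:
                eligible = [
                    v
                    for v in (baseline, followup)
                    if pid in intake.frames[v].index
                ]
        if not eligible:
            raise DataError(
                f"participant {pid!r} has no dietary assessment before "
                f"diagnosis (diagnosis_visit={dx})"
            )
        rows.append(
            np.mean([intake.frames[v].loc[pid].to_numpy() for v in eligible], axis=0)
        )
        energies.append(float(np.mean([intake.energy[v].loc[pid] for v in eligible])))
        ids.append(pid)

    idx = pd.Index(ids, name=cohort.index.name)
    return CumulativeIntake(
        intake=pd.DataFrame(rows, index=idx, columns=intake.foods),
        energy=pd.Series(energies, index=idx, name="energy_kcal"),
    )


# ---------------------------------------------------------------------------
# file readers / writers


def read_cohort(
    path,
    food_columns: Sequence[str] | None = None,
    food_prefix: str = "food_",
    sep: str = ",",
) -> tuple[pd.DataFrame, IntakeMatrix]:
    """Read a one-row-per-participant-visit CSV into cohort + intake.

    Food columns are identified by ``food_columns`` (explicit list) or by
    ``food_prefix``; the prefix is stripped to produce food-group names.
    Covariates are taken from the baseline row of each participant.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", "visit", "energy_kcal"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cohort file missing columns: {sorted(missing)}")
    if food_columns is None:
        food_cols = [c for c in df.columns if c.startswith(food_prefix)]
    else:
        food_cols = list(food_columns)
        absent = [c for c in food_cols if c not in df.columns]
        if absent:
            raise DataError(f"configured food columns not in file: {absent}")
    if not food_cols:
        raise DataError(f"no food columns found (prefix {food_prefix!r})")
    known = required | set(food_cols) | set(COHORT_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise DataError(f"unknown column(s) in cohort file: {unknown}")

    dup = df.duplicated(subset=["participant_id", "visit"])
    if dup.any():
        offenders = df.loc[dup, ["participant_id", "visit"]].to_records(index=False)
        raise DataError(f"duplicate participant-visit rows: {list(offenders)[:5]}")
    neg = df[food_cols].lt(0)
    if neg.any().any():
        row = neg.any(axis=1).idxmax()
        col = neg.loc[row].idxmax()
        raise DataError(
            f"negative intake for participant "
            f"{df.at[row, 'participant_id']!r}, column {col!r}"
        )

    strip = (lambda c: c[len(food_prefix):]) if food_columns is None else (lambda c: c)
    frames: dict[int, pd.DataFrame] = {}
    energy: dict[int, pd.Series] = {}
    for v, sub in df.groupby("visit"):
        sub = sub.set_index("participant_id")
        frames[int(v)] = sub[food_cols].rename(columns={c: strip(c) for c in food_cols})
        energy[int(v)] = sub["energy_kcal"]
    intake = IntakeMatrix(frames, energy)

    base = df[df["visit"] == min(frames)].set_index("participant_id")
    cohort_cols = [c for c in COHORT_COLUMNS if c in base.columns]
    cohort = base[cohort_cols].copy()
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            cohort[col] = np.nan
    cohort = cohort[list(COHORT_COLUMNS)]
    for col in ("education_high", "exercise_regular", "on_antidiabetic_meds",
                "incident_t2d"):
        if cohort[col].notna().all():
            cohort[col] = cohort[col].astype(bool)
    validate_cohort(cohort)
    return cohort, intake


def write_cohort(
    cohort: pd.DataFrame, intake: IntakeMatrix, path, food_prefix: str = "food_"
) -> None:
    """Inverse of :func:`read_cohort` (one row per participant-visit)."""
    parts = []
    for v in intake.visits:
        frame = intake.frames[v]
        block = frame.rename(columns={c: food_prefix + c for c in frame.columns})
        block = block.copy()
        block.insert(0, "visit", v)
        block["energy_kcal"] = intake.energy[v]
        if v == intake.baseline_visit:
            block = block.join(cohort, how="left")
        parts.append(block.reset_index(names="participant_id"))
    out = pd.concat(parts, ignore_index=True)
    out.to_csv(path, index=False)


EDGE_CSV_COLUMNS = ("food_a", "food_b", "weight", "sign", "n_iterations_significant")


def write_network(net, path, fmt: str = "edge_csv") -> None:
    """Write a co-consumption network as an edge-list CSV or GraphML file.

    The edge CSV keeps isolated nodes in a companion ``# nodes:`` header
    comment so the node universe round-trips.
    """
    graph = net.to_networkx() if hasattr(net, "to_networkx") else net
    if fmt == "edge_csv":
        rows = [
            {
                "food_a": a,
                "food_b": b,
                "weight": repr(float(d["weight"])),
                "sign": 1 if d["weight"] > 0 else -1,
                "n_iterations_significant": int(d.get("n_significant", 0)),
            }
            for a, b, d in sorted(graph.edges(data=True))
        ]
        with open(path, "w") as fh:
            fh.write("# nodes: " + ",".join(sorted(graph.nodes)) + "\n")
            if graph.graph.get("group"):
                fh.write(f"# group: {graph.graph['group']}\n")
            pd.DataFrame(rows, columns=EDGE_CSV_COLUMNS).to_csv(fh, index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise DataError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "edge_csv") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "edge_csv":
        raise DataError(f"unknown network format {fmt!r}")
    nodes: list[str] = []
    group = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# nodes:"):
            raw = line.split(":", 1)[1].strip()
            nodes = raw.split(",") if raw else []
        elif line.startswith("# group:"):
            group = line.split(":", 1)[1].strip()
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    graph = nx.Graph(group=group)
    graph.add_nodes_from(nodes)
    for _, row in df.iterrows():
        graph.add_edge(
            row["food_a"],
            row["food_b"],
            weight=float(row["weight"]),
            n_significant=int(row["n_iterations_significant"]),
        )
    return graph


SCORE_COLUMNS = ("participant_id", "diabetes_score", "non_diabetes_score",
                 "d_ccn", "quartile")


def write_scores(table: pd.DataFrame, path) -> None:
    out = table.reset_index(names="participant_id")
    cols = [c for c in SCORE_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("participant_id")
    return df
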