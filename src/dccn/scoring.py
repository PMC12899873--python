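"""Adaptive binarization and network-derived dietary scores.

Dietary intakes are zero-inflated and right-skewed, so "consumer" status
is defined per food by a hierarchical adaptive cut-point taken from that
food's own distribution: the first quartile if it is non-zero, else the
median if non-zero, else the third quartile if non-zero, else any positive
amount. A participant scores 1 for a food when intake is strictly above
the cut-point (ties at the cut-point count as non-consumers — staple foods
carry heavy ties at the quartiles, so the convention matters and is fixed
here).

The two network scores are weighted sums of the binarized intake, weighted
by each subnetwork's integrated centralities; the differential score
(``d_ccn``) is Diabetes Score − Non-diabetes Score. The whole module is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CumulativeIntake
from .errors import DataError

logger = logging.getLogger(__name__)

RULES = ("Q1", "median", "Q3", "any_positive")


@dataclass
class CutpointRule:
    """Per-food cut-point and the hierarchy rule that produced it."""

    cutpoints: dict[str, float]
    rules: dict[str, str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutpoint": self.cutpoints, "rule": self.rules}
        ).rename_axis("food")


def adaptive_cutpoints(
    intake: pd.DataFrame | CumulativeIntake,
    quantile_method: str = "linear",
) -> CutpointRule:
    """Hierarchical adaptive cut-points over the scoring population.

    Quartiles use linear interpolation on sorted values by default
    (``quantile_method`` accepts any numpy quantile method, e.g.
    ``"lower"`` for nearest-rank).
    """
    frame = intake.intake if isinstance(intake, CumulativeIntake) else intake
    cut: dict[str, float] = {}
    rules: dict[str, str] = {}
    for food in frame.columns:
        v = frame[food].to_numpy(dtype=float)
        if v.size == 0:
            raise DataError(f"empty intake column {food!r}")
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=quantile_method)
        if q1 > 0:
            cut[food], rules[food] = float(q1), "Q1"
        elif med > 0:
            cut[food], rules[food] = float(med), "median"
        elif q3 > 0:
            cut[food], rules[food] = float(q3), "Q3"
        else:
            cut[food], rules[food] = 0.0, "any_positive"
    return CutpointRule(cut, rules)


def binarize(
    intake: pd.DataFrame | CumulativeIntake, rule: CutpointRule
) -> pd.DataFrame:
    """0/1 consumer matrix: 1 iff intake strictly above the food's cut-point."""
    frame = intake.intake if isinstance(intake, CumulativeIntake) else intake
    missing = [f for f in frame.columns if f not in rule.cutpoints]
    if missing:
        raise DataError(f"foods missing from cut-point rule: {missing}")
    cuts = pd.Series(rule.cutpoints).reindex(frame.columns)
    return frame.gt(cuts, axis=1).astype(np.int8)


def score(
    binary: pd.DataFrame,
    weights_diabetic: dict[str, float],
    weights_nondiabetic: dict[str, float],
) -> pd.DataFrame:
    """Per-participant Diabetes, Non-diabetes and differential scores.

    Foods absent from a weight map contribute 0 to that score; a weight map
    naming a food absent from the binary matrix is an error (see
    :func:`transfer` for the cross-cohort policy).
    """
    table = pd.DataFrame(index=binary.index)
    for name, weights in (
        ("diabetes_score", weights_diabetic),
        ("non_diabetes_score", weights_nondiabetic),
    ):
        unknown = sorted(set(weights) - set(binary.columns))
        if unknown:
            raise DataError(f"weight map references unknown food(s): {unknown}")
        w = pd.Series(weights, dtype=float).reindex(binary.columns, fill_value=0.0)
        table[name] = binary.to_numpy() @ w.to_numpy()
    table["d_ccn"] = table["diabetes_score"] - table["non_diabetes_score"]
    return table


def transfer(
    weights_diabetic: dict[str, float],
    weights_nondiabetic: dict[str, float],
    intake: pd.DataFrame | CumulativeIntake,
    policy: str = "strict",
    name_map: dict[str, str] | None = None,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Score a target cohort with weights derived in another cohort.

    Cut-points are recomputed within the target cohort's own distribution;
    the weights are the source cohort's. ``name_map`` harmonizes source
    food names to target names. ``strict`` errors on any weighted food
    missing from the target; ``drop_missing`` logs and skips it.
    """
    if policy not in ("strict", "drop_missing"):
        raise DataError(f"unknown transfer policy {policy!r}")
    frame = intake.intake if isinstance(intake, CumulativeIntake) else intake
    name_map = name_map or {}

    def harmonize(weights: dict[str, float]) -> dict[str, float]:
        out = {}
        for food, w in weights.items():
            target = name_map.get(food, food)
            if target not in frame.columns:
                if policy == "strict":
                    raise DataError(
                        f"weighted food {food!r} (mapped to {target!r}) absent "
                        f"from target cohort"
                    )
                logger.warning("dropping weighted food %r absent from target", food)
                continue
            out[target] = w
        return out

    rule = adaptive_cutpoints(frame, quantile_method=quantile_method)
    binary = binarize(frame, rule)
    return score(binary, harmonize(weights_diabetic), harmonize(weights_nondiabetic))
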