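"""Numeric expression scores from categorical IHC annotations.

The atlas reports staining intensity (negative/weak/moderate/strong) and
the fraction of stained cells (<25%, 25-75%, >75%).  The default mapping
multiplies an intensity weight {0,1,2,3} by a fraction weight {1,2,4}, so
the maximum score is 12 — the same value the high-expression threshold
uses.  The mapping is a config block; everything downstream depends only
on the numeric matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .io import FRACTION_LEVELS, INTENSITY_LEVELS, StainingObservation

DEFAULT_INTENSITY_WEIGHTS = {"negative": 0.0, "weak": 1.0, "moderate": 2.0, "strong": 3.0}
DEFAULT_FRACTION_WEIGHTS = {"<25%": 1.0, "25-75%": 2.0, ">75%": 4.0}


@dataclass(frozen=True)
class ScoreMapping:
    """Intensity x fraction product mapping from categories to scores."""

    intensity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_WEIGHTS)
    )
    fraction_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_WEIGHTS)
    )

    def __post_init__(self) -> None:
        missing_i = set(INTENSITY_LEVELS) - set(self.intensity_weights)
        missing_f = set(FRACTION_LEVELS) - set(self.fraction_weights)
        if missing_i or missing_f:
            raise ValueError(
                f"score mapping incomplete; missing intensities {sorted(missing_i)} "
                f"and fractions {sorted(missing_f)}"
            )

    @property
    def max_score(self) -> float:
        return max(self.intensity_weights.values()) * max(self.fraction_weights.values())

    @classmethod
    def from_yaml(cls, path: str) -> "ScoreMapping":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            intensity_weights=cfg["intensity_weights"],
            fraction_weights=cfg["fraction_weights"],
        )


def score_observation(
    obs: StainingObservation, mapping: ScoreMapping | None = None
) -> float | None:
    """Score one observation; missing propagates to ``None``."""
    if obs.missing:
        return None
    mapping = mapping or ScoreMapping()
    return mapping.intensity_weights[obs.intensity] * mapping.fraction_weights[obs.fraction]


def build_expression_matrix(
    observations: Iterable[StainingObservation],
    mapping: ScoreMapping | None = None,
) -> pd.DataFrame:
    """Protein x sample score matrix; missing observations become NaN.

    Row order follows first appearance of each protein, column order first
    appearance of each sample.
    """
    mapping = mapping or ScoreMapping()
    rows: dict[str, dict[str, float]] = {}
    proteins: list[str] = []
    samples: list[str] = []
    for obs in observations:
        if obs.protein_id not in rows:
            rows[obs.protein_id] = {}
            proteins.append(obs.protein_id)
        if obs.sample_id not in samples:
            samples.append(obs.sample_id)
        score = score_observation(obs, mapping)
        rows[obs.protein_id][obs.sample_id] = math.nan if score is None else score
    mat = pd.DataFrame.from_dict(rows, orient="index")
    return mat.reindex(index=proteins, columns=samples)


def average_scores(matrix: pd.DataFrame, samples: list[str] | None = None) -> pd.Series:
    """Per-protein mean score over non-missing samples.

    Proteins missing in every (selected) sample are excluded from the
    result — the atlas deletion rule for all-"−" proteins.
    """
    sub = matrix[samples] if samples is not None else matrix
    means = sub.mean(axis=1, skipna=True)
    return means.dropna()


@dataclass
class ExpressionGroupSelection:
    """A named selection of proteins by expression level."""

    method: str
    parameter: float
    members: set[str]


_METHODS = ("top_fraction", "bottom_fraction", "threshold_high", "threshold_low")


def select_group(
    mean_scores: pd.Series, method: str, parameter: float
) -> ExpressionGroupSelection:
    """Select highly or lowly expressed proteins from mean scores.

    ``top_fraction``/``bottom_fraction`` take the ceil(f*n) most/least
    expressed proteins (ties at the boundary broken by protein id,
    ascending, for determinism); ``threshold_high``/``threshold_low`` are
    boundary-inclusive score cutoffs.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown selection method {method!r}; expected {_METHODS}")
    if len(mean_scores) == 0:
        raise ValueError("cannot select from an empty score map")
    if method in ("top_fraction", "bottom_fraction"):
        if not 0 < parameter <= 0.5:
            raise ValueError(f"fraction must lie in (0, 0.5], got {parameter}")
        n = len(mean_scores)
        k = math.ceil(parameter * n)
        df = pd.DataFrame({"score": mean_scores})
        df["pid"] = df.index
        ascending = method == "bottom_fraction"
        ordered = df.sort_values(["score", "pid"], ascending=[ascending, True])
        members = set(ordered.index[:k])
    elif method == "threshold_high":
        members = set(mean_scores.index[mean_scores >= parameter])
    else:
        members = set(mean_scores.index[mean_scores <= parameter])
    return ExpressionGroupSelection(method=method, parameter=parameter, members=members)


def write_selection(path: str, selection: ExpressionGroupSelection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={selection.method} parameter={selection.parameter}\n")
        fh.write("protein_id\n")
        for pid in sorted(selection.members):
            fh.write(pid + "\n")
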