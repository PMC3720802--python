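"""Peptidomimetic candidate enumeration, scoring and ranking.

Starting from a template peptide, constrained positions are substituted by
every residue in the scale table whose factor scores satisfy the position's
threshold rules (e.g. "integy moment > 2.0 and volume/shape > 2.0");
unconstrained positions keep the template residue.  The Cartesian product of
qualifying residues is scored with a fitted regression or discriminant model
and ranked by predicted activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .encoding import Peptide, encode_dataset, format_sequence
from .lda import LDAModel
from .pls import PLSModel
from .scales import ScaleTable

__all__ = [
    "DesignRule",
    "DesignCandidate",
    "qualifying_residues",
    "enumerate_candidates",
    "score_and_rank",
    "above_training_max",
]


@dataclass
class DesignRule:
    """Factor-score constraints on one 1-based template position.

    ``constraints`` is a list of (factor_name, comparator, threshold) with
    comparator ">" or "<"; all constraints must hold simultaneously.
    """

    position: int
    constraints: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("rule positions are 1-based")
        if not self.constraints:
            raise ValueError("a design rule needs at least one constraint")
        for name, op, thr in self.constraints:
            if op not in (">", "<"):
                raise ValueError(f"comparator must be '>' or '<', got {op!r}")
            float(thr)


@dataclass
class DesignCandidate:
    tokens: list[str]
    predicted_activity: float
    rank: int
    predicted_class: str | None = None

    @property
    def sequence(self) -> str:
        return format_sequence(self.tokens)


def qualifying_residues(rule: DesignRule, scales: ScaleTable) -> list[str]:
    """Residue ids in the scale table satisfying all of a rule's constraints,
    in scale-table row order."""
    df = scales.data
    mask = np.ones(len(df), dtype=bool)
    for name, op, thr in rule.constraints:
        if name not in df.columns:
            raise ValueError(
                f"unknown factor {name!r}; available: {list(df.columns)}"
            )
        col = df[name].to_numpy()
        mask &= (col > thr) if op == ">" else (col < thr)
    return [rid for rid, ok in zip(df.index, mask) if ok]


def enumerate_candidates(template: Peptide, rules: list[DesignRule],
                         scales: ScaleTable) -> list[Peptide]:
    """Cartesian-product enumeration of substitutions under the rules.

    Each constrained position ranges over its qualifying residues;
    unconstrained positions keep the template residue.  The result is
    deduplicated and sorted lexicographically by token ids so enumeration
    order is deterministic.
    """
    L = len(template)
    by_pos: dict[int, DesignRule] = {}
    for rule in rules:
        if rule.position > L:
            raise ValueError(
                f"rule position {rule.position} exceeds template length {L}"
            )
        if rule.position in by_pos:
            raise ValueError(f"duplicate rule for position {rule.position}")
        by_pos[rule.position] = rule

    pools: list[list[str]] = []
    for pos in range(1, L + 1):
        if pos in by_pos:
            pool = qualifying_residues(by_pos[pos], scales)
            if not pool:
                warnings.warn(
                    f"no residue satisfies the constraints at position {pos}; "
                    "enumeration is empty"
                )
                return []
            pools.append(pool)
        else:
            pools.append([template.tokens[pos - 1]])

    seen = set()
    combos = []
    for combo in product(*pools):
        if combo not in seen:
            seen.add(combo)
            combos.append(combo)
    combos.sort()
    return [
        Peptide(tokens=list(c), sample_id=format_sequence(list(c)))
        for c in combos
    ]


def score_and_rank(candidates: list[Peptide], model, scales: ScaleTable
                   ) -> list[DesignCandidate]:
    """Score candidates with a fitted PLS or LDA model and rank them.

    Regression models rank by predicted activity; discriminant models by the
    posterior probability of the positive class.  Ties break
    lexicographically by token ids; ranks are dense starting at 1.
    """
    if not candidates:
        return []
    mat = encode_dataset(candidates, scales)
    if isinstance(model, PLSModel):
        preds = model.predict(mat.values)
        classes = [None] * len(candidates)
    elif isinstance(model, LDAModel):
        preds = model.posterior_positive(mat.values)
        labels = model.predict(mat.values)
        classes = [str(c) for c in labels]
    else:
        raise TypeError(f"cannot score with model of type {type(model).__name__}")

    order = sorted(
        range(len(candidates)),
        key=lambda i: (-preds[i], tuple(candidates[i].tokens)),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        out.append(DesignCandidate(
            tokens=list(candidates[i].tokens),
            predicted_activity=float(preds[i]),
            rank=rank,
            predicted_class=classes[i],
        ))
    return out


def above_training_max(ranked: list[DesignCandidate], y_train
                       ) -> list[DesignCandidate]:
    """Candidates predicted strictly above the best observed training
    activity."""
    y = np.asarray(y_train, float).ravel()
    cutoff = float(y.max())
    return [c for c in ranked if c.predicted_activity > cutoff]
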