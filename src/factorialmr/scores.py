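"""Weighted genetic scores: weight tables, scoring, median splits, 2x2 allocation.

A weighted genetic score sums per-variant effect-allele dosages weighted by
the per-allele effect of that variant on a trait, so the score is expressed
in trait units (mg/dL for the lipid scores): S_i = sum_j g_ij * beta_j.
Weights are stored trait-increasing; "genetically lower" groups fall out of
the median split, not of any sign flip of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeightTable",
    "FactorialAllocation",
    "FACTORIAL_GROUPS",
    "read_weights",
    "compute_score",
    "dichotomize",
    "allocate_factorial",
]

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "eaf", "beta", "trait")
_VALID_ALLELES = frozenset("ACGT")

#: Factorial group labels, reference first.
FACTORIAL_GROUPS = ("both_higher", "lowerA_only", "lowerB_only", "both_lower")


@dataclass
class WeightTable:
    """Per-variant effect-allele weights defining one genetic score.

    ``beta`` is the per-effect-allele change in the trait (trait units);
    ``eaf`` the effect-allele frequency.  ``trait`` labels the score and
    ``unit`` its physical unit ("mg/dL" for lipid scores).
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    eaf: np.ndarray
    beta: np.ndarray
    trait: str
    unit: str = "mg/dL"

    def __post_init__(self):
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.eaf = np.asarray(self.eaf, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.variant_id)

    def validate(self) -> None:
        n = len(self.variant_id)
        if not (len(self.effect_allele) == len(self.eaf) == len(self.beta) == n):
            raise ValueError("weight table columns have unequal lengths")
        ids, counts = np.unique(self.variant_id, return_counts=True)
        if np.any(counts > 1):
            dups = list(ids[counts > 1])
            raise ValueError(f"duplicate variant_id in weight table: {dups}")
        if n and (np.any(self.eaf <= 0) or np.any(self.eaf >= 1)):
            bad = list(self.variant_id[(self.eaf <= 0) | (self.eaf >= 1)])
            raise ValueError(f"eaf must lie in (0,1); offending variants: {bad}")
        if n and np.any(~np.isfinite(self.beta)):
            bad = list(self.variant_id[~np.isfinite(self.beta)])
            raise ValueError(f"beta must be finite; offending variants: {bad}")
        bad_alleles = [a for a in self.effect_allele if a not in _VALID_ALLELES]
        if bad_alleles:
            raise ValueError(f"effect_allele must be one of A/C/G/T, got {bad_alleles}")

    # -- expected moments of the score under Hardy-Weinberg dosages ---------
    def expected_score_mean(self) -> float:
        return float(np.sum(2.0 * self.eaf * self.beta))

    def expected_score_var(self) -> float:
        return float(np.sum(2.0 * self.eaf * (1.0 - self.eaf) * self.beta**2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "effect_allele": self.effect_allele,
                "eaf": self.eaf,
                "beta": self.beta,
                "trait": self.trait,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights(path, unit: str = "mg/dL") -> WeightTable:
    """Parse a tab-separated weight table.

    Expected header: ``variant_id  effect_allele  eaf  beta  trait``.
    Malformed rows raise with the 1-based line number; range violations
    (eaf outside (0,1), non-finite beta) raise a validation error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(WEIGHT_COLUMNS):
            raise ValueError(
                f"{path}: header {header!r} does not match expected {list(WEIGHT_COLUMNS)}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(WEIGHT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(WEIGHT_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], parts[1], float(parts[2]), float(parts[3]), parts[4])
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    traits = {r[4] for r in rows}
    if len(traits) > 1:
        raise ValueError(f"{path}: multiple trait labels in one table: {sorted(traits)}")
    trait = rows[0][4] if rows else path.stem
    return WeightTable(
        variant_id=[r[0] for r in rows],
        effect_allele=[r[1] for r in rows],
        eaf=np.array([r[2] for r in rows], dtype=float),
        beta=np.array([r[3] for r in rows], dtype=float),
        trait=trait,
        unit=unit,
    )


def compute_score(dosages: pd.DataFrame, weights: WeightTable) -> np.ndarray:
    """Weighted allele score S_i = sum_j g_ij * beta_j in trait units.

    ``dosages`` columns are matched to the weight table by variant id, so
    column order is irrelevant.  Variants present in the weights but absent
    from the dosages raise, listing the missing ids.
    """
    if len(weights) == 0:
        raise ValueError(f"weight table for trait {weights.trait!r} is empty")
    missing = [v for v in weights.variant_id if v not in dosages.columns]
    if missing:
        raise KeyError(f"dosage matrix lacks variants required by the score: {missing}")
    G = dosages.loc[:, list(weights.variant_id)].to_numpy(dtype=float)
    return G @ weights.beta


def dichotomize(scores) -> np.ndarray:
    """Median split into 'lower' / 'higher' groups.

    Individuals at or below the sample median are 'lower' (ties go to the
    lower group, keeping the split deterministic).  Constant score vectors
    cannot be split and raise.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 individuals to median-split")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.all(s == s[0]):
        raise ValueError("score vector is constant; median split impossible")
    med = float(np.median(s))
    labels = np.where(s <= med, "lower", "higher")
    if (labels == "lower").all() or (labels == "higher").all():
        # e.g. scores {0,0,0,1}: median 0 sends all-but-one to 'lower';
        # only truly constant vectors reach an empty group, handled above,
        # but guard against pathological float medians anyway.
        raise ValueError("median split produced an empty group")
    return labels


@dataclass
class FactorialAllocation:
    """Cross-classification by two median-split scores into four subgroups.

    The reference group is higher on both scores (higher predicted levels of
    both traits, i.e. the untreated analog of a 2x2 factorial trial).
    """

    group: np.ndarray  # entries from FACTORIAL_GROUPS
    score_a: str = "A"
    score_b: str = "B"

    def counts(self) -> pd.Series:
        return pd.Series(
            {g: int(np.sum(self.group == g)) for g in FACTORIAL_GROUPS}, name="n"
        )

    def indicator(self, group_name: str) -> np.ndarray:
        if group_name not in FACTORIAL_GROUPS:
            raise KeyError(f"unknown factorial group {group_name!r}")
        return (self.group == group_name).astype(float)

    def __len__(self) -> int:
        return len(self.group)


def allocate_factorial(scores_a, scores_b, labels: tuple[str, str] = ("A", "B")) -> FactorialAllocation:
    """Allocate individuals to the 2x2 factorial subgroups.

    Each score is split at its own median (`dichotomize`); the four cells are
    the cross-classification, mimicking random allocation in a factorial
    trial because genotypes assort independently.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    low_a = dichotomize(a) == "lower"
    low_b = dichotomize(b) == "lower"
    group = np.empty(a.shape, dtype=object)
    group[~low_a & ~low_b] = "both_higher"
    group[low_a & ~low_b] = "lowerA_only"
    group[~low_a & low_b] = "lowerB_only"
    group[low_a & low_b] = "both_lower"
    return FactorialAllocation(group=group, score_a=labels[0], score_b=labels[1])
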