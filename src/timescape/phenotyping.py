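"""Cell phenotyping from marker intensities: thresholds, gating rules, H-scores.

Phenotypes are assigned by intensity thresholding against a prioritized rule
set (subtype rules like CTL beat their parent rules like T). The taxonomy is
deliberately overlapping for reporting purposes — a CD3+CD8+ cell is both a
CTL and a T cell — so classification emits, besides the single
highest-priority ``phenotype`` label, one boolean ``is_<type>`` column per
rule recording plain rule satisfaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeRule",
    "HScoreInput",
    "compute_hscore",
    "threshold_positive",
    "classify_cells",
    "cell_type_proportions",
    "default_rules",
    "default_thresholds",
    "otsu_threshold",
    "PHENOTYPE_MARKERS",
    "INFLAMMATORY_MARKERS",
    "CELL_TYPES",
]

PHENOTYPE_MARKERS = ["CD3", "CD4", "CD8", "CD20", "CD68", "CD163", "NKp46", "SOX10"]
INFLAMMATORY_MARKERS = ["CD74", "CD44", "MIF", "iNOS", "mPGES1", "NT"]

#: The 8-type reporting taxonomy (overlapping: T ⊇ CTL ∪ Th, TAM ⊇ M2).
CELL_TYPES = ["B", "T", "Th", "CTL", "NK", "TAM", "M2", "Tumor"]


@dataclass(frozen=True)
class PhenotypeRule:
    """A gating rule: all ``positive`` markers above threshold, all
    ``negative`` markers below. Lower ``priority`` wins for the exclusive
    ``phenotype`` label."""

    name: str
    positive: frozenset
    negative: frozenset = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError(f"rule {self.name!r}: positive/negative markers overlap")
        if not self.positive:
            raise ValueError(f"rule {self.name!r}: needs at least one positive marker")


def default_rules() -> list[PhenotypeRule]:
    """Default 8-type gating hierarchy.

    Exact NK/M2 gating markers vary by antibody panel; NKp46 and CD163 are
    configurable stand-ins. Subtypes (CTL, Th, M2) outrank parents (T, TAM).
    """
    r = PhenotypeRule
    return [
        r("Tumor", frozenset({"SOX10"}), priority=0),
        r("CTL", frozenset({"CD3", "CD8"}), priority=1),
        r("Th", frozenset({"CD3", "CD4"}), priority=2),
        r("M2", frozenset({"CD68", "CD163"}), priority=3),
        r("B", frozenset({"CD20"}), priority=4),
        r("NK", frozenset({"NKp46"}), priority=5),
        r("TAM", frozenset({"CD68"}), priority=6),
        r("T", frozenset({"CD3"}), priority=7),
    ]


def default_thresholds(markers=None, value: float = 3.0) -> dict:
    """Flat per-marker positivity thresholds (intensity units)."""
    if markers is None:
        markers = PHENOTYPE_MARKERS + INFLAMMATORY_MARKERS
    return {m: value for m in markers}


@dataclass(frozen=True)
class HScoreInput:
    """Percentages of cells staining at 1+, 2+ and 3+ intensity bins."""

    pct_1plus: float
    pct_2plus: float
    pct_3plus: float

    def __post_init__(self) -> None:
        for v in (self.pct_1plus, self.pct_2plus, self.pct_3plus):
            if not (0.0 <= v <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")
        if self.pct_1plus + self.pct_2plus + self.pct_3plus > 100.0 + 1e-9:
            raise ValueError("intensity-bin percentages sum above 100")


def compute_hscore(inp: HScoreInput | tuple) -> float:
    """Semi-quantitative staining score in [0, 300].

    H-score = (% of 1+ × 1) + (% of 2+ × 2) + (% of 3+ × 3); 0 is fully
    negative tissue, 300 is 100% of cells staining at 3+ intensity.
    """
    if not isinstance(inp, HScoreInput):
        inp = HScoreInput(*inp)
    return inp.pct_1plus * 1 + inp.pct_2plus * 2 + inp.pct_3plus * 3


def threshold_positive(intensity, threshold: float):
    """Closed-bound positivity: intensity >= threshold."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensities must be nonnegative")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    out = intensity >= threshold
    return bool(out) if out.ndim == 0 else out


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's between-class-variance threshold on log-intensities.

    Optional automatic alternative to fixed thresholds; off by default.
    """
    v = np.log(np.asarray(values, dtype=float) + 1e-12)
    hist, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    k = int(np.nanargmax(sigma_b))
    return float(np.exp(centers[k]))


def _rule_mask(cells: pd.DataFrame, rule: PhenotypeRule, thresholds: dict) -> np.ndarray:
    mask = np.ones(len(cells), dtype=bool)
    for m in rule.positive:
        mask &= threshold_positive(cells[m].to_numpy(), thresholds[m])
    for m in rule.negative:
        mask &= ~threshold_positive(cells[m].to_numpy(), thresholds[m])
    return mask


def classify_cells(
    cells: pd.DataFrame,
    rules: list[PhenotypeRule] | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Assign phenotypes by prioritized threshold gating.

    Returns a copy of ``cells`` with a ``phenotype`` column (highest-priority
    satisfied rule, else ``"other"``) and one ``is_<name>`` boolean column per
    rule (rule satisfaction regardless of priority, supporting the
    overlapping taxonomy). Deterministic and invariant to row order.
    """
    if rules is None:
        rules = default_rules()
    if thresholds is None:
        thresholds = default_thresholds()
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    for rule in rules:
        for m in rule.positive | rule.negative:
            if m not in thresholds:
                raise KeyError(f"rule {rule.name!r} references marker {m!r} with no threshold")
            if m not in cells.columns:
                raise KeyError(f"rule {rule.name!r} references marker {m!r} with no intensity column")
    out = cells.copy()
    label = np.full(len(out), "other", dtype=object)
    assigned = np.zeros(len(out), dtype=bool)
    for rule in sorted(rules, key=lambda r: r.priority):
        mask = _rule_mask(out, rule, thresholds)
        out[f"is_{rule.name}"] = mask
        take = mask & ~assigned
        label[take] = rule.name
        assigned |= mask
    out["phenotype"] = label
    return out


def cell_type_proportions(
    cells: pd.DataFrame, taxonomy: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample cell-type proportions over all cells in the sample.

    Uses the overlapping ``is_<type>`` columns when present (so T counts
    include CTL and Th), falling back to the exclusive ``phenotype`` label.
    The denominator is always the total cell count of the sample, so rows
    need not sum to 1. Samples with zero cells cannot occur in a row-per-cell
    table; an empty input yields an empty result.
    """
    if taxonomy is None:
        taxonomy = CELL_TYPES
    if "phenotype" not in cells.columns:
        raise ValueError("cells must be classified first (no phenotype column)")
    records = {}
    for sid, sub in cells.groupby("sample_id", sort=True):
        n = len(sub)
        rec = {}
        for t in taxonomy:
            col = f"is_{t}"
            cnt = int(sub[col].sum()) if col in sub.columns else int((sub["phenotype"] == t).sum())
            rec[t] = cnt / n
        records[sid] = rec
    out = pd.DataFrame.from_dict(records, orient="index", columns=taxonomy)
    out.index.name = "sample_id"
    return out
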