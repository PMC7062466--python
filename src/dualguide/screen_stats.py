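"""Viability-screen outcome classification and essentiality benchmarking.

A cross is scored from adult counts: *lethal* when no correct-genotype adults
eclose, *semi-lethal* when correct-genotype adults are present but number less
than half the balancer-class adults, *viable* otherwise. Benchmarking compares
outcomes against curated essentiality annotations: the false-negative rate is
the percentage of viable outcomes among lines targeting essential genes, the
false-positive rate the percentage of lethal outcomes among lines targeting
nonessential genes. Lines with unknown annotation are counted but excluded
from both rate denominators.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOMES = ("lethal", "semi_lethal", "viable", "unscored")
ANNOTATIONS = ("essential", "nonessential", "unknown")

SEMI_LETHAL_RATIO = 0.5  # correct-genotype adults < 50% of balancer-class adults


def classify_cross(n_correct: int, n_balancer: int) -> str:
    """Outcome from adult counts; monotone in n_correct for fixed n_balancer."""
    if n_correct < 0 or n_balancer < 0:
        raise ValueError("counts must be non-negative")
    if n_correct == 0:
        if n_balancer == 0:
            logger.warning("cross with zero flies of either class: low-confidence lethal")
        return "lethal"
    if n_correct < SEMI_LETHAL_RATIO * n_balancer:
        return "semi_lethal"
    return "viable"


@dataclass
class ScreenRecord:
    line_id: str
    gene_id: str
    n_correct: int | None = None
    n_balancer: int | None = None
    outcome: str | None = None  # None -> unscored
    annotation: str = "unknown"

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.annotation not in ANNOTATIONS:
            raise ValueError(f"unknown annotation {self.annotation!r}")
        if self.n_correct is not None and self.n_balancer is not None:
            derived = classify_cross(self.n_correct, self.n_balancer)
            if self.outcome is None:
                self.outcome = derived
            elif self.outcome != derived and self.outcome != "unscored":
                logger.warning(
                    "line %s: recorded outcome %s inconsistent with counts (%d, %d -> %s); "
                    "keeping recorded outcome",
                    self.line_id, self.outcome, self.n_correct, self.n_balancer, derived,
                )

    @property
    def effective_outcome(self) -> str:
        return self.outcome if self.outcome is not None else "unscored"


def percent(numerator: int, denominator: int, rounding: str = "half_away") -> int | None:
    """Integer percentage; ``half_away`` rounds halves away from zero, ``floor`` truncates."""
    if denominator == 0:
        return None
    x = 100.0 * numerator / denominator
    if rounding == "floor":
        return int(math.floor(x))
    if rounding != "half_away":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class BenchmarkSummary:
    n_total: int
    outcome_counts: dict[str, int]
    outcome_percentages: dict[str, int]
    class_totals: dict[str, int]
    class_counts: dict[str, dict[str, int]]
    class_percentages: dict[str, dict[str, int | None]]
    fn_rate: int | None  # % viable among essential-annotated
    fp_rate: int | None  # % lethal among nonessential-annotated

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "outcome_counts": self.outcome_counts,
            "outcome_percentages": self.outcome_percentages,
            "class_totals": self.class_totals,
            "class_counts": self.class_counts,
            "class_percentages": self.class_percentages,
            "fn_rate": self.fn_rate,
            "fp_rate": self.fp_rate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ann in ANNOTATIONS:
            for out in OUTCOMES:
                rows.append({
                    "annotation": ann,
                    "outcome": out,
                    "count": self.class_counts[ann].get(out, 0),
                    "percent": self.class_percentages[ann].get(out),
                })
        return pd.DataFrame(rows)


def benchmark(records: list[ScreenRecord], rounding: str = "half_away") -> BenchmarkSummary:
    """Summarise outcomes overall and per annotation class.

    Overall percentages use the full line count as denominator (unscored lines
    included); class rates use the class totals.
    """
    if not records:
        raise ValueError("cannot benchmark an empty record list")
    n = len(records)
    outcome_counts = {o: 0 for o in OUTCOMES}
    class_totals = {a: 0 for a in ANNOTATIONS}
    class_counts = {a: {o: 0 for o in OUTCOMES} for a in ANNOTATIONS}
    for r in records:
        o = r.effective_outcome
        outcome_counts[o] += 1
        class_totals[r.annotation] += 1
        class_counts[r.annotation][o] += 1
    outcome_pct = {o: percent(c, n, rounding) for o, c in outcome_counts.items()}
    class_pct = {
        a: {o: percent(class_counts[a][o], class_totals[a], rounding) for o in OUTCOMES}
        for a in ANNOTATIONS
    }
    return BenchmarkSummary(
        n_total=n,
        outcome_counts=outcome_counts,
        outcome_percentages=outcome_pct,
        class_totals=class_totals,
        class_counts=class_counts,
        class_percentages=class_pct,
        fn_rate=class_pct["essential"]["viable"],
        fp_rate=class_pct["nonessential"]["lethal"],
    )


@dataclass(frozen=True)
class ScreenSimParams:
    """Generative parameters of a synthetic viability screen.

    Defaults mirror the benchmarked screen: 210 lines on essential genes and
    54 on nonessential ones, with 79% of essential-gene lines lethal and 89%
    of nonessential-gene lines viable; the non-detected remainder splits
    between semi-lethal and the opposite extreme by ``semi_lethal_fraction``
    (20 of the 43 non-lethal essential-gene lines were semi-lethal, ~0.47).
    """

    n_essential: int = 210
    n_nonessential: int = 54
    sensitivity: float = 0.79  # P(lethal | essential)
    specificity: float = 0.89  # P(viable | nonessential)
    semi_lethal_fraction: float = 0.47
    mean_balancer: int = 40

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "semi_lethal_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


def simulate_screen(params: ScreenSimParams, seed: int) -> list[ScreenRecord]:
    """Synthetic screen records with counts consistent with each outcome."""
    rng = np.random.default_rng(seed)
    records: list[ScreenRecord] = []

    def counts_for(outcome: str) -> tuple[int, int]:
        nb = max(4, int(rng.poisson(params.mean_balancer)))
        half = int(math.ceil(SEMI_LETHAL_RATIO * nb))
        if outcome == "lethal":
            return 0, nb
        if outcome == "semi_lethal":
            return int(rng.integers(1, max(2, half))), nb
        return int(rng.integers(half, nb + half)), nb

    i = 0
    for _ in range(params.n_essential):
        u = rng.random()
        if u < params.sensitivity:
            outcome = "lethal"
        elif rng.random() < params.semi_lethal_fraction:
            outcome = "semi_lethal"
        else:
            outcome = "viable"
        nc, nb = counts_for(outcome)
        records.append(ScreenRecord(f"line{i:05d}", f"ess{i:05d}", nc, nb,
                                    annotation="essential"))
        i += 1
    for _ in range(params.n_nonessential):
        u = rng.random()
        if u < params.specificity:
            outcome = "viable"
        elif rng.random() < params.semi_lethal_fraction:
            outcome = "semi_lethal"
        else:
            outcome = "lethal"
        nc, nb = counts_for(outcome)
        records.append(ScreenRecord(f"line{i:05d}", f"non{i:05d}", nc, nb,
                                    annotation="nonessential"))
        i += 1
    return records


def read_screen_table(path) -> list[ScreenRecord]:
    """TSV reader; count columns and the outcome column are each optional."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "gene_id": str})
    required = {"line_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"screen table must provide columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def intval(key):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)

        outcome = d.get("outcome")
        if not isinstance(outcome, str):
            outcome = None
        annotation = d.get("annotation", "unknown")
        if not isinstance(annotation, str):
            annotation = "unknown"
        records.append(ScreenRecord(
            line_id=d["line_id"],
            gene_id=d["gene_id"],
            n_correct=intval("n_correct"),
            n_balancer=intval("n_balancer"),
            outcome=outcome,
            annotation=annotation,
        ))
    return records


def write_screen_records(records: list[ScreenRecord], path) -> None:
    pd.DataFrame([
        {
            "line_id": r.line_id, "gene_id": r.gene_id,
            "n_correct": r.n_correct, "n_balancer": r.n_balancer,
            "outcome": r.effective_outcome, "annotation": r.annotation,
        }
        for r in records
    ]).to_csv(path, sep="\t", index=False)
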