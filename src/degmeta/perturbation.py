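"""Rule-based classification of in-vivo perturbation evidence.

Candidate hub genes are validated against published perturbation
experiments in murine MS models (EAE / chronic relapsing EAE).  Each
experiment perturbs one gene — reducing its activity (knockout,
knockdown, inhibiting treatment) or increasing it (overexpression,
activating treatment) — and reports a clinical readout (amelioration,
exacerbation, no effect).  The classification is a fixed truth table:

* reduction -> amelioration, or increase -> exacerbation: the gene is
  *detrimental* to the disease model;
* reduction -> exacerbation, or increase -> amelioration: *beneficial*;
* no effect on the model: *no_effect* evidence.

Per-gene tallies then give a net call (detrimental / beneficial / mixed /
none); the raw counts are reported alongside so unbalanced mixed evidence
is never hidden behind a single label.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "GeneEffectTally",
    "INCREASING_PERTURBATIONS",
    "MODELS",
    "OUTCOMES",
    "PERTURBATIONS",
    "PerturbationRecord",
    "REDUCING_PERTURBATIONS",
    "classify_perturbation",
    "read_perturbation_table",
    "tally_gene_effects",
    "tally_to_frame",
]

REDUCING_PERTURBATIONS = frozenset({"knockout", "knockdown", "inhibiting_treatment"})
INCREASING_PERTURBATIONS = frozenset({"overexpression", "activating_treatment"})
PERTURBATIONS = REDUCING_PERTURBATIONS | INCREASING_PERTURBATIONS
OUTCOMES = frozenset({"amelioration", "exacerbation", "no_effect"})
MODELS = frozenset({"EAE", "CREAE"})


@dataclass(frozen=True)
class PerturbationRecord:
    """One published in-vivo perturbation experiment."""

    gene: str
    perturbation: str
    outcome: str
    model: str = "EAE"
    citation: str = ""

    def __post_init__(self) -> None:
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


def classify_perturbation(rec: PerturbationRecord) -> str:
    """Effect label for one experiment: detrimental / beneficial / no_effect."""
    if rec.outcome == "no_effect":
        return "no_effect"
    reduced = rec.perturbation in REDUCING_PERTURBATIONS
    ameliorated = rec.outcome == "amelioration"
    # reduction+amelioration and increase+exacerbation both mean the gene
    # drives pathology; the other two pairings mean it protects.
    return "detrimental" if reduced == ameliorated else "beneficial"


@dataclass(frozen=True)
class GeneEffectTally:
    """Per-gene evidence counts and net call."""

    gene: str
    n_detrimental: int
    n_beneficial: int
    n_no_effect: int
    net: str  # detrimental | beneficial | mixed | none

    @property
    def n_experiments(self) -> int:
        return self.n_detrimental + self.n_beneficial + self.n_no_effect


def tally_gene_effects(records: Sequence[PerturbationRecord]) -> list[GeneEffectTally]:
    """Tally classified experiments per gene.

    Net call: detrimental if detrimental evidence outnumbers beneficial,
    beneficial in the opposite case, mixed when both are present and
    balanced, none when only no-effect experiments exist.  Genes with no
    records are simply absent.  The tally is invariant to record order.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {"detrimental": 0, "beneficial": 0, "no_effect": 0})
    for rec in records:
        counts[rec.gene][classify_perturbation(rec)] += 1
    out = []
    for gene in sorted(counts):
        c = counts[gene]
        if c["detrimental"] > c["beneficial"]:
            net = "detrimental"
        elif c["beneficial"] > c["detrimental"]:
            net = "beneficial"
        elif c["detrimental"] > 0:  # equal and nonzero
            net = "mixed"
        else:
            net = "none"
        out.append(GeneEffectTally(gene, c["detrimental"], c["beneficial"], c["no_effect"], net))
    return out


def read_perturbation_table(path, *, sep: str = "\t") -> list[PerturbationRecord]:
    """Load a perturbation annotation TSV (gene, perturbation, outcome, model, citation)."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    needed = {"gene", "perturbation", "outcome"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    return [
        PerturbationRecord(
            gene=row["gene"],
            perturbation=row["perturbation"],
            outcome=row["outcome"],
            model=row.get("model") or "EAE",
            citation=row.get("citation", ""),
        )
        for _, row in df.iterrows()
    ]


def tally_to_frame(tallies: Sequence[GeneEffectTally]) -> pd.DataFrame:
    """Stacked-bar-chart-ready table of per-gene evidence counts."""
    return pd.DataFrame(
        [
            {
                "gene": t.gene,
                "detrimental": t.n_detrimental,
                "beneficial": t.n_beneficial,
                "no_effect": t.n_no_effect,
                "net": t.net,
            }
            for t in tallies
        ]
    )
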