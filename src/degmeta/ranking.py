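"""Vote-count ranking of genes across independent study DEG lists.

A gene consistently reported with the same fold-change direction in many
independent studies is more likely to reflect a real pathological process
than a gene appearing once.  The ranking applies three ordered criteria:

1. number of study lists agreeing on the gene's direction,
2. total number of samples contributed by the agreeing comparisons,
3. mean |log2 fold change| over the agreeing comparisons.

Direction agreement uses a strict-majority rule: the modal direction
defines the agreeing subset; exact up/down ties make the gene
"inconsistent", which ranks after every consistent gene.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .ingest import DEGRecord

__all__ = [
    "GeneSupport",
    "OverlapProfile",
    "count_overlap_levels",
    "rank_genes",
    "tabulate_gene_support",
    "write_ranking",
]


@dataclass(frozen=True)
class GeneSupport:
    """Cross-study support tally for one gene."""

    entrez_id: int
    gene_symbol: str
    direction: str                      # "up" | "down" | "inconsistent"
    n_agree: int                        # lists with the modal direction
    studies_agree: frozenset[str]
    n_samples_agree: int                # sample sum over agreeing comparisons
    mean_fc_agree: float                # mean log2FC over agreeing comparisons
    n_total: int                        # lists containing the gene at all

    def __post_init__(self) -> None:
        if self.n_agree > self.n_total:
            raise ValueError("n_agree cannot exceed n_total")
        if self.n_agree == 0 and self.n_samples_agree != 0:
            raise ValueError("n_samples_agree must be 0 when no list agrees")


def tabulate_gene_support(
    study_lists: Sequence[Sequence[DEGRecord]],
    *,
    samples_unit: str = "tissues",
) -> list[GeneSupport]:
    """Tally per-gene cross-study support from merged per-study lists.

    Each inner sequence is one study's merged list (at most one record per
    gene — duplicates are an input-contract error).  ``samples_unit``
    selects whether criterion 2 sums tissue samples (default) or brain
    donors; the donor variant requires donor counts on the records.
    """
    if samples_unit not in ("tissues", "donors"):
        raise ValueError(f"samples_unit must be 'tissues' or 'donors', got {samples_unit!r}")

    per_gene: dict[int, list[DEGRecord]] = defaultdict(list)
    for study in study_lists:
        seen: set[int] = set()
        for rec in study:
            if rec.entrez_id is None:
                raise ValueError(f"unmapped record {rec.study_id}/{rec.gene_symbol}")
            if rec.entrez_id in seen:
                raise ValueError(
                    f"duplicate gene {rec.entrez_id} in study {rec.study_id}; "
                    "merge within study first"
                )
            seen.add(rec.entrez_id)
            per_gene[rec.entrez_id].append(rec)

    def samples(rec: DEGRecord) -> int:
        if samples_unit == "tissues":
            return rec.n_samples
        if rec.n_ms_donors is None or rec.n_ctrl_donors is None:
            raise ValueError(f"record {rec.study_id}/{rec.gene_symbol} lacks donor counts")
        return rec.n_ms_donors + rec.n_ctrl_donors

    out: list[GeneSupport] = []
    for entrez, recs in per_gene.items():
        ups = [r for r in recs if r.log2fc > 0]
        downs = [r for r in recs if r.log2fc <= 0]
        if len(ups) > len(downs):
            direction, agree = "up", ups
        elif len(downs) > len(ups):
            direction, agree = "down", downs
        else:
            direction, agree = "inconsistent", []
        out.append(
            GeneSupport(
                entrez_id=entrez,
                gene_symbol=recs[0].gene_symbol,
                direction=direction,
                n_agree=len(agree),
                studies_agree=frozenset(r.study_id for r in agree),
                n_samples_agree=sum(samples(r) for r in agree),
                mean_fc_agree=(sum(r.log2fc for r in agree) / len(agree)) if agree else 0.0,
                n_total=len(recs),
            )
        )
    return out


def rank_genes(support: Sequence[GeneSupport]) -> list[GeneSupport]:
    """Order genes by the three vote-count criteria, in order of relevance.

    Descending lexicographic sort on (n_agree, n_samples_agree,
    |mean_fc_agree|); residual ties break on ascending Entrez id so output
    files are reproducible.  Inconsistent genes sort after all consistent
    ones (they have n_agree = 0 by construction, but the flag is enforced
    explicitly).
    """
    return sorted(
        support,
        key=lambda s: (
            s.direction == "inconsistent",
            -s.n_agree,
            -s.n_samples_agree,
            -abs(s.mean_fc_agree),
            s.entrez_id,
        ),
    )


@dataclass
class OverlapProfile:
    """How many genes are supported at each agreement level.

    ``counts_by_level[k]`` counts genes with a consistent direction in
    exactly ``k`` lists; ``total_multi`` sums levels >= 2 (the multi-study
    genes the overlap test is about).
    """

    counts_by_level: dict[int, int] = field(default_factory=dict)
    total_multi: int = 0
    n_inconsistent: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts_by_level": {str(k): v for k, v in sorted(self.counts_by_level.items())},
                "total_multi": self.total_multi,
                "n_inconsistent": self.n_inconsistent,
            },
            indent=2,
        )


def count_overlap_levels(support: Sequence[GeneSupport]) -> OverlapProfile:
    """Count genes per agreement level k and total multi-study genes (k >= 2)."""
    counts: dict[int, int] = defaultdict(int)
    n_inconsistent = 0
    for s in support:
        if s.direction == "inconsistent":
            n_inconsistent += 1
        else:
            counts[s.n_agree] += 1
    total_multi = sum(v for k, v in counts.items() if k >= 2)
    return OverlapProfile(dict(counts), total_multi, n_inconsistent)


def write_ranking(path, ranked: Sequence[GeneSupport]) -> None:
    """Write the ranked gene table as TSV (mirrors the supplementary ranking tables)."""
    rows = [
        {
            "rank": i,
            "entrez_id": s.entrez_id,
            "gene_symbol": s.gene_symbol,
            "direction": s.direction,
            "n_agree": s.n_agree,
            "studies_agree": ",".join(sorted(s.studies_agree)),
            "n_samples_agree": s.n_samples_agree,
            "mean_fc_agree": s.mean_fc_agree,
        }
        for i, s in enumerate(ranked, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
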