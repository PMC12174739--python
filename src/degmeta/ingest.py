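"""Reading, validating, filtering and merging per-study DEG lists.

Each included study reports one or more case-vs-control comparisons of MS
white-matter tissue (normal-appearing white matter, active lesions, chronic
active lesions) against control white matter, as a table of differentially
expressed genes (DEGs) with fold changes and significance values.  This
module turns those heterogeneous tables into a canonical representation:
one :class:`DEGRecord` per gene per comparison, filtered by a per-study
:class:`FilterPolicy`, mapped to Entrez identifiers, and finally collapsed
to one record per gene per study (keeping the comparison with the largest
absolute log2 fold change).
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Comparison",
    "DEGRecord",
    "FilterMode",
    "FilterPolicy",
    "FilterStats",
    "GeneIdMap",
    "MergeResult",
    "ReadResult",
    "apply_significance_filter",
    "map_gene_ids",
    "merge_within_study",
    "read_deg_table",
    "read_gene_id_map",
    "write_merged_lists",
]


class Comparison(str, Enum):
    """Tissue comparison a DEG list originates from."""

    NAWM_VS_CTRL = "NAWM_vs_ctrl"
    AL_VS_CTRL = "AL_vs_ctrl"
    CAL_VS_CTRL = "CAL_vs_ctrl"
    OTHER = "other"


#: Priority used to break opposite-sign |log2FC| ties within a study.
#: Later lesion stages rank higher (chronic active > active > NAWM).
COMPARISON_PRIORITY: dict[Comparison, int] = {
    Comparison.CAL_VS_CTRL: 3,
    Comparison.AL_VS_CTRL: 2,
    Comparison.NAWM_VS_CTRL: 1,
    Comparison.OTHER: 0,
}


@dataclass(frozen=True)
class DEGRecord:
    """One gene's reported differential expression in one comparison of one study.

    ``log2fc`` is the canonical effect size; when a study reports a linear
    fold change it is converted on ingest (see :func:`linear_to_log2fc`).
    Sample counts refer to tissue samples by default; donor counts may be
    carried separately when a study reports both.
    """

    study_id: str
    comparison: Comparison
    gene_symbol: str
    log2fc: float
    entrez_id: int | None = None
    fold_change_linear: float | None = None
    p_value: float | None = None
    adj_p_value: float | None = None
    n_ms_samples: int = 0
    n_ctrl_samples: int = 0
    n_ms_donors: int | None = None
    n_ctrl_donors: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_value", "adj_p_value"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1] for {self.gene_symbol}")
        if self.n_ms_samples < 0 or self.n_ctrl_samples < 0:
            raise ValueError("sample counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.n_ms_samples + self.n_ctrl_samples


def linear_to_log2fc(x: float) -> float:
    """Convert a linear fold change to log2 scale.

    Down-regulation reported sign-magnitude style (e.g. ``-2.0`` meaning
    two-fold down) maps to ``-log2(|x|)``; ratios in (0, 1) map through the
    plain logarithm.  ``x == 0`` and ``|x| == 0`` are invalid.
    """
    if x == 0:
        raise ValueError("linear fold change of 0 cannot be converted")
    if x < 0:
        return -math.log2(abs(x))
    return math.log2(x)


class FilterMode(str, Enum):
    """Which significance rule a study's DEG list was (re)filtered with."""

    LOG2FC_P = "log2fc_p"          # |log2FC| > 1 and p < 0.05 (default rule)
    LINEAR_FC_ONLY = "linear_fc_only"  # linear |FC| >= 2.5 (Baranzini-style)
    P_ONLY = "p_only"              # p < 0.025 (Lindberg-style)
    ADJ_P_ONLY = "adj_p_only"      # Benjamini-Hochberg adjusted p < 0.05


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for one study's significance filter.

    The default policy is the shared rule applied to most studies:
    ``|log2FC| > 1`` together with ``p < 0.05``.  The alternative modes
    encode the per-study exceptions (linear fold-change threshold 2.5,
    nominal p < 0.025, BH-adjusted p < 0.05).
    """

    mode: FilterMode = FilterMode.LOG2FC_P
    log2fc_threshold: float = 1.0
    p_threshold: float = 0.05
    linear_fc_threshold: float = 2.5
    adj_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("log2fc_threshold", "p_threshold", "linear_fc_threshold", "adj_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Per-study filter exceptions shipped as a preset (overridable in run config).
STUDY_FILTER_PRESETS: dict[str, FilterPolicy] = {
    "Baranzini2000": FilterPolicy(mode=FilterMode.LINEAR_FC_ONLY, linear_fc_threshold=2.5),
    "Lindberg2004": FilterPolicy(mode=FilterMode.P_ONLY, p_threshold=0.025),
    "Melief2019": FilterPolicy(mode=FilterMode.ADJ_P_ONLY, adj_p_threshold=0.05),
}


class ReadResult(NamedTuple):
    records: list[DEGRecord]
    row_errors: list[tuple[int, str]]  # (1-based data row number, message)


def read_deg_table(
    path,
    schema: Mapping[str, str],
    *,
    study_id: str | None = None,
    comparison: Comparison | str | None = None,
    fc_scale: str = "log2",
    sep: str | None = None,
) -> ReadResult:
    """Read a delimited DEG table into :class:`DEGRecord` objects.

    Parameters
    ----------
    schema
        Maps DEGRecord field names to column names in the file.  Mandatory
        keys: ``gene_symbol`` and ``fold_change``.  Optional keys:
        ``study_id``, ``comparison``, ``entrez_id``, ``p_value``,
        ``adj_p_value``, ``n_ms_samples``, ``n_ctrl_samples``.
    study_id, comparison
        Constants applied to every row when not provided as columns.
    fc_scale
        ``"log2"`` if the fold-change column is already on log2 scale,
        ``"linear"`` if it is a (possibly sign-magnitude) linear ratio.
        Studies do not all report on the same scale, so the caller declares
        it per table.

    Malformed rows (non-numeric fold change, out-of-range p-values) are
    skipped and reported with their row numbers rather than aborting the read.
    """
    if fc_scale not in ("log2", "linear"):
        raise ValueError(f"fc_scale must be 'log2' or 'linear', got {fc_scale!r}")
    for required in ("gene_symbol", "fold_change"):
        if required not in schema:
            raise ValueError(f"schema is missing mandatory key {required!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise ValueError(f"columns named by schema absent from {path}: {missing}")

    records: list[DEGRecord] = []
    row_errors: list[tuple[int, str]] = []

    def get(row, key, default=None):
        col = schema.get(key)
        if col is None:
            return default
        v = row[col]
        return default if pd.isna(v) else v

    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            fc_raw = float(get(row, "fold_change"))
            if fc_scale == "linear":
                fold_change_linear = fc_raw
                log2fc = linear_to_log2fc(fc_raw)
            else:
                fold_change_linear = None
                log2fc = fc_raw
            p_value = get(row, "p_value")
            adj_p_value = get(row, "adj_p_value")
            entrez = get(row, "entrez_id")
            rec = DEGRecord(
                study_id=str(get(row, "study_id", study_id)),
                comparison=Comparison(get(row, "comparison", comparison or Comparison.OTHER)),
                gene_symbol=str(get(row, "gene_symbol")).strip(),
                log2fc=log2fc,
                fold_change_linear=fold_change_linear,
                entrez_id=int(entrez) if entrez is not None else None,
                p_value=float(p_value) if p_value is not None else None,
                adj_p_value=float(adj_p_value) if adj_p_value is not None else None,
                n_ms_samples=int(get(row, "n_ms_samples", 0)),
                n_ctrl_samples=int(get(row, "n_ctrl_samples", 0)),
            )
        except (TypeError, ValueError) as exc:
            row_errors.append((i, str(exc)))
            continue
        records.append(rec)
    if row_errors:
        logger.warning("%s: skipped %d malformed rows", path, len(row_errors))
    return ReadResult(records, row_errors)


class FilterStats(NamedTuple):
    n_kept: int
    n_removed: int
    n_missing_field: int  # removed because the mode's required field was absent


def _passes(rec: DEGRecord, policy: FilterPolicy) -> bool | None:
    """True/False if testable; None when the record lacks the required field."""
    if policy.mode is FilterMode.LOG2FC_P:
        if rec.p_value is None:
            return None
        return abs(rec.log2fc) > policy.log2fc_threshold and rec.p_value < policy.p_threshold
    if policy.mode is FilterMode.LINEAR_FC_ONLY:
        linear = rec.fold_change_linear
        magnitude = abs(linear) if linear is not None else 2.0 ** abs(rec.log2fc)
        return magnitude >= policy.linear_fc_threshold
    if policy.mode is FilterMode.P_ONLY:
        if rec.p_value is None:
            return None
        return rec.p_value < policy.p_threshold
    if policy.mode is FilterMode.ADJ_P_ONLY:
        if rec.adj_p_value is None:
            return None
        return rec.adj_p_value < policy.adj_p_threshold
    raise ValueError(f"unknown filter mode {policy.mode!r}")


def apply_significance_filter(
    records: Sequence[DEGRecord], policy: FilterPolicy | None = None
) -> tuple[list[DEGRecord], FilterStats]:
    """Retain records passing the policy's conjunction of threshold tests.

    Records lacking the field the mode requires are excluded and counted
    separately (never silently kept).
    """
    policy = policy or FilterPolicy()
    kept: list[DEGRecord] = []
    n_removed = 0
    n_missing = 0
    for rec in records:
        verdict = _passes(rec, policy)
        if verdict is None:
            n_missing += 1
            logger.debug("record %s/%s lacks field required by %s", rec.study_id, rec.gene_symbol, policy.mode)
        elif verdict:
            kept.append(rec)
        else:
            n_removed += 1
    return kept, FilterStats(len(kept), n_removed, n_missing)


@dataclass
class GeneIdMap:
    """Local gene symbol -> Entrez id mapping with manual overrides.

    Overrides take precedence over the base mapping; they hold the
    hand-curated identifiers for symbols the mapping table does not
    recognise (aliases, withdrawn symbols).
    """

    mapping: dict[str, int] = field(default_factory=dict)
    manual_overrides: dict[str, int] = field(default_factory=dict)

    def lookup(self, symbol: str) -> int | None:
        if symbol in self.manual_overrides:
            return self.manual_overrides[symbol]
        return self.mapping.get(symbol)

    def __len__(self) -> int:
        return len(set(self.mapping) | set(self.manual_overrides))


def read_gene_id_map(path, *, sep: str = "\t") -> GeneIdMap:
    """Load a two-column (symbol, entrez_id) mapping table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (symbol, entrez_id)")
    symbols = df.iloc[:, 0].astype(str)
    ids = df.iloc[:, 1].astype(int)
    return GeneIdMap(mapping=dict(zip(symbols, ids)))


def map_gene_ids(
    records: Sequence[DEGRecord], idmap: GeneIdMap
) -> tuple[list[DEGRecord], dict[str, Counter]]:
    """Attach Entrez ids; return mapped records and a per-study unmapped report.

    Records whose symbol is in neither the mapping nor the overrides are
    excluded from the output and tallied in the report
    (``{study_id: Counter(symbol -> occurrences)}``).
    """
    if len(idmap) == 0:
        raise ValueError("gene id map is empty; load a mapping table first")
    mapped: list[DEGRecord] = []
    unmapped: dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        entrez = idmap.lookup(rec.gene_symbol)
        if entrez is None:
            unmapped[rec.study_id][rec.gene_symbol] += 1
        else:
            mapped.append(replace(rec, entrez_id=entrez))
    if unmapped:
        n = sum(sum(c.values()) for c in unmapped.values())
        logger.info("%d records with unmapped symbols excluded", n)
    return mapped, dict(unmapped)


class MergeResult(NamedTuple):
    records: list[DEGRecord]
    opposite_sign_ties: list[tuple[str, int]]  # (study_id, entrez_id) flagged


def merge_within_study(records: Sequence[DEGRecord]) -> MergeResult:
    """Collapse to one record per (study, gene), keeping the largest |log2FC|.

    A gene reported in several comparisons of the same study keeps the
    record with the highest absolute log2 fold change.  Exact |log2FC| ties
    with the same sign collapse silently; opposite-sign ties are resolved
    by comparison priority (CAL > AL > NAWM > other) and flagged, so that
    directional ambiguity is deterministic rather than input-order dependent.
    """
    groups: dict[tuple[str, int], list[DEGRecord]] = defaultdict(list)
    for rec in records:
        if rec.entrez_id is None:
            raise ValueError(f"record {rec.study_id}/{rec.gene_symbol} not mapped to an Entrez id")
        groups[(rec.study_id, rec.entrez_id)].append(rec)

    merged: list[DEGRecord] = []
    ties: list[tuple[str, int]] = []
    for key, group in groups.items():
        best_abs = max(abs(r.log2fc) for r in group)
        best = [r for r in group if abs(r.log2fc) == best_abs]
        signs = {r.log2fc > 0 for r in best}
        if len(signs) > 1:
            ties.append(key)
            logger.warning(
                "opposite-sign |log2FC| tie for study %s gene %s; resolved by comparison priority",
                key[0], key[1],
            )
        # Priority then comparison value keeps selection deterministic.
        chosen = max(best, key=lambda r: (COMPARISON_PRIORITY[r.comparison], r.comparison.value))
        merged.append(chosen)
    merged.sort(key=lambda r: (r.study_id, r.entrez_id))
    return MergeResult(merged, ties)


def write_merged_lists(path, records: Iterable[DEGRecord]) -> None:
    """Write canonical merged per-study gene lists as TSV."""
    rows = [
        {
            "study_id": r.study_id,
            "entrez_id": r.entrez_id,
            "gene_symbol": r.gene_symbol,
            "log2fc": r.log2fc,
            "n_ms_samples": r.n_ms_samples,
            "n_ctrl_samples": r.n_ctrl_samples,
            "comparison_of_origin": r.comparison.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
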