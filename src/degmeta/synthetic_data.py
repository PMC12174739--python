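"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage is testable offline: this module generates

* an expression matrix with block-correlated gene modules (shared latent
  factor construction, so the expected within-module correlation is exact),
* per-study DEG tables mixing a planted set of consistently deregulated
  genes with direction-random background genes, all passing the default
  significance filter,
* a STRING-style PPI edge list with planted dense complexes on a sparse
  background, and
* a perturbation table whose records invert the effect truth table, so
  classification must recover each gene's planted effect.

Gene identities are integer Entrez-style ids ``1..n_universe_genes`` with
display symbols ``SYN00001`` etc.  All generators are deterministic given
the config seed; independent streams per generator are derived from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import Comparison, DEGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticPPI",
    "SyntheticStudies",
    "SynthesisConfig",
    "simulate_expression",
    "simulate_perturbations",
    "simulate_ppi",
    "simulate_studies",
    "write_fixture_set",
]

_COMPARISON_CYCLE = (Comparison.NAWM_VS_CTRL, Comparison.AL_VS_CTRL, Comparison.CAL_VS_CTRL)


@dataclass
class SynthesisConfig:
    """Study conditions for the synthetic fixture set.

    The defaults emulate the integrated meta-analysis at desk scale: a
    2,000-gene universe observed in 50 samples, 8 co-expression modules
    with within-module correlation 0.7, 9 independent study lists, and 50
    planted genes each present in a given list with probability 0.6 and a
    fully consistent fold-change direction.  List sizes (20-40 genes) are
    deliberately small relative to the universe so that chance
    identity-overlap — including its inflation under connectivity-weighted
    sampling — stays well below the planted signal; see the methods note
    for the calculation behind this choice.
    """

    seed: int = 0
    n_universe_genes: int = 2000
    n_samples: int = 50
    n_modules: int = 8
    within_module_cor: float = 0.7
    n_studies: int = 9
    list_size_range: tuple[int, int] = (20, 40)
    planted_gene_count: int = 50
    planted_presence_prob: float = 0.6
    planted_direction_consistency: float = 1.0
    background_direction_split: float = 0.5
    plant_in_modules: bool = True
    ppi_complex_sizes: tuple[int, ...] = (12, 14, 16)
    ppi_intra_p: float = 0.9
    ppi_background_p: float = 0.05
    ppi_n_background_genes: int = 100

    def __post_init__(self) -> None:
        for name in ("within_module_cor", "planted_presence_prob",
                     "planted_direction_consistency", "background_direction_split",
                     "ppi_intra_p", "ppi_background_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.list_size_range
        if not (0 < lo <= hi <= self.n_universe_genes):
            raise ValueError(f"invalid list_size_range {self.list_size_range}")
        if self.planted_gene_count > lo:
            logger.warning(
                "planted_gene_count (%d) exceeds the minimum list size (%d); "
                "lists may be dominated by planted genes",
                self.planted_gene_count, lo,
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of this config."""
        return np.random.default_rng([self.seed, stream])

    @property
    def universe(self) -> np.ndarray:
        return np.arange(1, self.n_universe_genes + 1)


def gene_symbol(entrez: int) -> str:
    return f"SYN{entrez:05d}"


def module_sizes(cfg: SynthesisConfig) -> np.ndarray:
    """Gene count per module: geometrically growing, smallest module first.

    Real co-expression networks have very uneven module sizes; a geometric
    progression (ratio 1.25) paired with stronger correlation in smaller
    modules gives the connectivity heterogeneity that makes the
    soft-threshold scale-free fit attainable.
    """
    w = 1.25 ** np.arange(cfg.n_modules)
    sizes = np.floor(cfg.n_universe_genes * w / w.sum()).astype(int)
    sizes[-1] += cfg.n_universe_genes - sizes.sum()  # remainder to the largest
    return sizes


def module_assignment(cfg: SynthesisConfig) -> np.ndarray:
    """Module index per gene (contiguous blocks; every gene is assigned)."""
    return np.repeat(np.arange(cfg.n_modules), module_sizes(cfg))


def module_strengths(cfg: SynthesisConfig) -> np.ndarray:
    """Within-module correlation per module.

    Linearly spread around the configured level (factor 1.35 for the
    smallest, strongest module down to 0.85 for the largest), clipped to
    [0, 0.95].  The pair-weighted mean stays near the configured value
    while the spread, amplified by the soft-threshold power, produces a
    decaying connectivity distribution.
    """
    factors = np.linspace(1.35, 0.85, cfg.n_modules)
    return np.clip(cfg.within_module_cor * factors, 0.0, 0.95)


def simulate_expression(cfg: SynthesisConfig) -> pd.DataFrame:
    """Block-correlated expression matrix (genes x samples).

    Gene g in module m is ``sqrt(rho_m) * l_g * f_m + sqrt(1 - rho_m *
    l_g^2) * eps_g`` with standard normal factor and noise and a per-gene
    loading ``l_g ~ U(0.9, 1.1)``, giving expected pairwise correlation
    ``rho_m * l_i * l_j`` within a module and 0 across modules.  The
    loading spread smooths the connectivity distribution so it is not a
    sum of point masses.
    """
    rng = cfg.rng(1)
    modules = module_assignment(cfg)
    rho = module_strengths(cfg)[modules]
    loading = rng.uniform(0.9, 1.1, size=cfg.n_universe_genes)
    signal_var = np.clip(rho * loading ** 2, 0.0, 0.99)
    factors = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    noise = rng.standard_normal((cfg.n_universe_genes, cfg.n_samples))
    values = (
        np.sqrt(signal_var)[:, None] * factors[modules]
        + np.sqrt(1.0 - signal_var)[:, None] * noise
    )
    return pd.DataFrame(
        values,
        index=pd.Index(cfg.universe, name="entrez_id"),
        columns=[f"sample{j + 1}" for j in range(cfg.n_samples)],
    )


@dataclass
class SyntheticStudies:
    """Per-study DEG tables with their planted ground truth."""

    tables: dict[str, pd.DataFrame]
    planted: np.ndarray                     # planted entrez ids
    truth_direction: dict[int, str]         # planted id -> "up" | "down"
    config: SynthesisConfig = field(repr=False, default=None)

    @property
    def list_sizes(self) -> list[int]:
        return [len(t) for t in self.tables.values()]

    def records(self) -> list[list[DEGRecord]]:
        """Tables as merged per-study record lists ready for tabulation."""
        out = []
        for study_id, df in self.tables.items():
            out.append(
                [
                    DEGRecord(
                        study_id=study_id,
                        comparison=Comparison(row.comparison),
                        gene_symbol=row.gene_symbol,
                        entrez_id=int(row.entrez_id),
                        log2fc=float(row.log2fc),
                        p_value=float(row.p_value),
                        adj_p_value=float(row.adj_p_value),
                        n_ms_samples=int(row.n_ms_samples),
                        n_ctrl_samples=int(row.n_ctrl_samples),
                    )
                    for row in df.itertuples(index=False)
                ]
            )
        return out


def simulate_studies(cfg: SynthesisConfig) -> SyntheticStudies:
    """Generate the per-study DEG lists.

    Each study's list holds the planted genes present in that study
    (presence probability and direction consistency from the config) plus
    uniformly sampled background genes with random directions, up to the
    study's drawn list size.  Effect sizes exceed |log2FC| = 1 and
    p-values fall below 0.05, so every record passes the default filter;
    tissue sample counts are drawn per study.
    """
    rng = cfg.rng(2)
    modules = module_assignment(cfg)
    universe = cfg.universe

    if cfg.plant_in_modules:
        # bias the signal into the strongest (highest-connectivity) modules,
        # which is the harder condition for the weighted null
        eligible = universe[modules < max(1, cfg.n_modules // 2)]
    else:
        eligible = universe
    planted = np.sort(rng.choice(eligible, size=cfg.planted_gene_count, replace=False))
    truth = {int(g): ("up" if rng.random() < 0.5 else "down") for g in planted}
    background_pool = np.setdiff1d(universe, planted)

    tables: dict[str, pd.DataFrame] = {}
    for s in range(cfg.n_studies):
        study_id = f"S{s + 1}"
        comparison = _COMPARISON_CYCLE[s % len(_COMPARISON_CYCLE)]
        n_ms = int(rng.integers(4, 13))
        n_ctrl = int(rng.integers(4, 13))
        size = int(rng.integers(cfg.list_size_range[0], cfg.list_size_range[1] + 1))

        present = planted[rng.random(cfg.planted_gene_count) < cfg.planted_presence_prob]
        n_background = max(0, size - len(present))
        background = rng.choice(background_pool, size=n_background, replace=False)

        rows = []
        for g in present:
            direction = truth[int(g)]
            if rng.random() >= cfg.planted_direction_consistency:
                direction = "down" if direction == "up" else "up"
            rows.append((int(g), direction))
        for g in background:
            rows.append((int(g), "up" if rng.random() < cfg.background_direction_split else "down"))

        genes = np.array([g for g, _ in rows])
        signs = np.array([1.0 if d == "up" else -1.0 for _, d in rows])
        magnitudes = 1.05 + rng.exponential(0.8, size=len(rows))
        p_values = rng.uniform(1e-8, 0.0499, size=len(rows))
        adj_p = np.minimum(p_values * rng.uniform(1.0, 3.0, size=len(rows)), 0.9999)
        tables[study_id] = pd.DataFrame(
            {
                "study_id": study_id,
                "comparison": comparison.value,
                "gene_symbol": [gene_symbol(g) for g in genes],
                "entrez_id": genes,
                "log2fc": signs * magnitudes,
                "p_value": p_values,
                "adj_p_value": adj_p,
                "n_ms_samples": n_ms,
                "n_ctrl_samples": n_ctrl,
            }
        )
    return SyntheticStudies(tables, planted, truth, cfg)


@dataclass
class SyntheticPPI:
    edges: pd.DataFrame                     # node1, node2, combined_score
    complexes: list[frozenset]              # planted dense complexes


def simulate_ppi(cfg: SynthesisConfig, genes=None) -> SyntheticPPI:
    """PPI edge list with planted dense complexes on a sparse background.

    Complexes are Erdos-Renyi-dense blocks (``ppi_intra_p``) over disjoint
    gene subsets; pairs involving at least one background gene connect
    with ``ppi_background_p``.  Distinct complexes are not wired to each
    other directly — they are independent planted units reachable only
    through background genes, whose low vertex weights stop cluster
    expansion (a direct inter-complex edge would merge two equal-density
    complexes under any seeded-expansion detector).  Edge scores sit above
    the default confidence threshold, so the graph structure — not the
    score filter — carries the signal.
    """
    rng = cfg.rng(3)
    n_complex_genes = sum(cfg.ppi_complex_sizes)
    if genes is None:
        n = n_complex_genes + cfg.ppi_n_background_genes
        genes = cfg.universe[:n]
    genes = np.asarray(genes)
    if len(genes) < n_complex_genes:
        raise ValueError("not enough genes for the configured complex sizes")

    shuffled = rng.permutation(genes)
    complexes = []
    offset = 0
    membership = {}
    for ci, size in enumerate(cfg.ppi_complex_sizes):
        block = shuffled[offset:offset + size]
        complexes.append(frozenset(int(g) for g in block))
        for g in block:
            membership[int(g)] = ci
        offset += size

    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    gi, gj = shuffled[iu], shuffled[ju]
    mi = np.array([membership.get(int(a), -1) for a in gi])
    mj = np.array([membership.get(int(b), -1) for b in gj])
    same = (mi == mj) & (mi >= 0)
    cross_complex = (mi >= 0) & (mj >= 0) & (mi != mj)
    p_edge = np.where(same, cfg.ppi_intra_p,
                      np.where(cross_complex, 0.0, cfg.ppi_background_p))
    keep = rng.random(len(p_edge)) < p_edge
    scores = rng.integers(600, 1000, size=int(keep.sum()))
    edges = pd.DataFrame(
        {
            "node1": gi[keep].astype(int),
            "node2": gj[keep].astype(int),
            "combined_score": scores,
        }
    )
    return SyntheticPPI(edges, complexes)


def simulate_perturbations(
    cfg: SynthesisConfig, genes, truth: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Perturbation table whose records encode a known per-gene effect.

    Each gene gets 1-3 experiments drawn as the inverse of the effect
    truth table: a detrimental gene yields reduction->amelioration or
    increase->exacerbation records (and vice versa); a no-effect gene
    yields only no_effect outcomes.  Returns the table and the truth map.
    """
    rng = cfg.rng(4)
    genes = [str(g) for g in genes]
    if truth is None:
        labels = ("detrimental", "beneficial", "none")
        truth = {g: labels[i % 3] for i, g in enumerate(genes)}
    reducing = ("knockout", "knockdown", "inhibiting_treatment")
    increasing = ("overexpression", "activating_treatment")
    rows = []
    for g in genes:
        for _ in range(int(rng.integers(1, 4))):
            model = "EAE" if rng.random() < 0.8 else "CREAE"
            effect = truth[g]
            if effect == "none":
                pert = rng.choice(reducing + increasing)
                outcome = "no_effect"
            else:
                if rng.random() < 0.5:
                    pert = rng.choice(reducing)
                    outcome = "amelioration" if effect == "detrimental" else "exacerbation"
                else:
                    pert = rng.choice(increasing)
                    outcome = "exacerbation" if effect == "detrimental" else "amelioration"
            rows.append(
                {
                    "gene": g,
                    "perturbation": str(pert),
                    "outcome": outcome,
                    "model": model,
                    "citation": f"synthetic:{g}",
                }
            )
    return pd.DataFrame(rows), truth


def write_fixture_set(cfg: SynthesisConfig, outdir) -> dict:
    """Emit the full fixture set as TSVs plus a manifest JSON.

    Writes the expression matrix, one DEG table per study, the
    symbol->Entrez id map, the PPI edge list, the perturbation table and a
    ``manifest.json`` recording the seed and the planted ground truth.
    Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = simulate_expression(cfg)
    expr.to_csv(outdir / "expression.tsv", sep="\t")

    studies = simulate_studies(cfg)
    for study_id, df in studies.tables.items():
        df.to_csv(outdir / f"deg_{study_id}.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"gene_symbol": [gene_symbol(g) for g in cfg.universe], "entrez_id": cfg.universe}
    ).to_csv(outdir / "id_map.tsv", sep="\t", index=False)

    ppi = simulate_ppi(cfg)
    ppi.edges.to_csv(outdir / "ppi.tsv", sep="\t", index=False)

    hub_genes = sorted({g for c in ppi.complexes for g in c})[:30]
    pert, pert_truth = simulate_perturbations(cfg, hub_genes)
    pert.to_csv(outdir / "perturbations.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "n_universe_genes": cfg.n_universe_genes,
        "n_studies": cfg.n_studies,
        "planted_genes": [int(g) for g in studies.planted],
        "truth_direction": {str(k): v for k, v in studies.truth_direction.items()},
        "ppi_complexes": [sorted(c) for c in ppi.complexes],
        "perturbation_truth": pert_truth,
        "files": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
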