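"""miRNA/mRNA functional-pair inference and generic set-enrichment arithmetic.

A functional pair couples a differentially expressed miRNA family
with target genes moving in the opposite direction. Three criteria
must hold for a family to be reported:

  i)  anti-correlated expression: the family is differentially
      expressed in one direction and the candidate genes in the other;
  ii) a predicted seed-site interaction (the family's TargetIndex);
  iii) target enrichment: the selected (opposite-direction) gene list
      contains significantly more of the family's targets than
      expected from its target count in the background, by the
      one-sided (upper-tail) hypergeometric test.

The same hypergeometric/fold-enrichment/BH machinery also serves
generic gene-set (e.g. gene-ontology) term enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .diffexpr import DifferentialCall
from .seed_targets import TargetIndex

__all__ = [
    "EnrichmentRow",
    "FunctionalPairReport",
    "hypergeom_enrichment",
    "functional_pairs",
    "term_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    """One family/term row of a hypergeometric enrichment table.

    k of the n selected genes are targets/annotated; K of the N
    background genes are. fold_enrichment = (k/n)/(K/N).
    """

    name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fold_enrichment: float
    fdr: float = float("nan")


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts targets among n genes drawn without replacement from a
    background of N genes of which K are targets. Evaluated via the
    log-space survival function for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N; got k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    if n == 0 or K == 0:
        return float("nan")
    return (k / n) / (K / N)


@dataclass
class FunctionalPairReport:
    """Families passing all three criteria, with their gene-level pairs."""

    rows: list[EnrichmentRow] = field(default_factory=list)
    pairs: dict = field(default_factory=dict)       # family -> sorted gene list
    all_rows: list = field(default_factory=list)    # every tested family (pre-alpha)
    mirna_direction: str = "down"
    gene_direction: str = "up"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [r.name for r in self.rows],
                "count_in_selected_genes": [r.k for r in self.rows],
                "count_in_total_pop": [r.K for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "fold_enrichment": [r.fold_enrichment for r in self.rows],
                "fdr": [r.fdr for r in self.rows],
            }
        )


def _sorted_rows(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    # ascending p, then descending k, then name
    return sorted(rows, key=lambda r: (r.p_value, -r.k, r.name))


def functional_pairs(
    de_genes: list[DifferentialCall],
    de_mirnas: list[DifferentialCall],
    index: TargetIndex,
    background: list[str],
    config: PipelineConfig | None = None,
) -> FunctionalPairReport:
    """Apply the three functional-pair criteria family by family.

    With the default ``down-vs-up`` direction, each downregulated
    miRNA family (passing the DE thresholds) is tested against the
    upregulated gene list: k = selected genes among its targets,
    K = background genes among its targets, n = |selected|,
    N = |background|. Families with p <= enrichment_alpha are
    reported, with BH-FDR computed across all tested families.
    """
    config = config or PipelineConfig()
    if config.mirna_direction == "down-vs-up":
        mdir, gdir = "down", "up"
    else:
        mdir, gdir = "up", "down"
    background_set = set(background)
    selected = [c.feature for c in de_genes if c.passes and c.direction == gdir]
    missing = set(selected) - background_set
    if missing:
        raise ValueError(f"selected genes absent from background: {sorted(missing)[:5]}")
    selected_set = set(selected)
    n = len(selected_set)
    N = len(background_set)
    candidates = [c.feature for c in de_mirnas if c.passes and c.direction == mdir]

    report = FunctionalPairReport(mirna_direction=mdir, gene_direction=gdir)
    if n == 0:
        logger.info("no %sregulated genes selected; empty functional-pair report", gdir)
        return report
    tested = []
    for fam in candidates:
        targets = index.genes_for(fam) & background_set
        K = len(targets)
        k = len(targets & selected_set)
        if K == 0:
            logger.info("family %s has no targets in background; skipped", fam)
            continue
        p = hypergeom_enrichment(k, K, n, N)
        tested.append(EnrichmentRow(name=fam, k=k, K=K, n=n, N=N, p_value=p,
                                    fold_enrichment=_fold_enrichment(k, K, n, N)))
    if tested:
        _, fdrs, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, q in zip(tested, fdrs):
            r.fdr = float(q)
    report.all_rows = _sorted_rows(tested)
    report.rows = [r for r in report.all_rows if r.p_value <= config.enrichment_alpha]
    for r in report.rows:
        report.pairs[r.name] = sorted(index.genes_for(r.name) & selected_set)
    return report


def term_enrichment(
    selected: list[str],
    gene_sets: list[tuple[str, str, list[str]]],
    background: list[str],
) -> list[EnrichmentRow]:
    """Hypergeometric term enrichment over GMT-style gene sets.

    Counts are restricted to the background; sets with no background
    members are skipped with a logged notice. BH-FDR is computed
    across the tested sets; rows come back sorted by ascending p.
    """
    background_set = set(background)
    selected_set = set(selected)
    stray = selected_set - background_set
    if stray:
        raise ValueError(f"selected genes absent from background: {sorted(stray)[:5]}")
    n, N = len(selected_set), len(background_set)
    rows = []
    for name, _desc, genes in gene_sets:
        members = set(genes) & background_set
        K = len(members)
        if K == 0:
            logger.info("gene set %s has no background members; skipped", name)
            continue
        k = len(members & selected_set)
        rows.append(EnrichmentRow(name=name, k=k, K=K, n=n, N=N,
                                  p_value=hypergeom_enrichment(k, K, n, N),
                                  fold_enrichment=_fold_enrichment(k, K, n, N)))
    if rows:
        _, fdrs, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
    return _sorted_rows(rows)
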