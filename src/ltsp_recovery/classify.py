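"""RNA-polymerase-core allele classification and recovery outcomes.

Three convergent sites in the RNA polymerase core enzyme (RNAPC) —
RpoB residue 1272, RpoC residue 334 and RpoC residue 428 — carry the
antagonistically pleiotropic adaptations (anRNAPC) that are adaptive
under long-term stationary phase but costly for regrowth.  Each clone
is put in exactly one category: the matching anRNAPC site, another
RNAPC mutation, or none, with anRNAPC taking precedence.

When a founder clone fixed for an anRNAPC allele is propagated, its
descendants are scored as ``reversion`` (the founder's allele — same
position, same alt allele — is gone), ``compensation`` (the allele is
retained and at least one additional RNAPC mutation appeared), or
``retained``.  Reversion is nucleotide-level: a second same-codon
substitution restoring the ancestral amino acid but not the ancestral
nucleotide counts as compensation, because the founder's derived allele
is still present at the nucleotide the classifier keys on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .mutations import CloneGenotype, Mutation

logger = logging.getLogger(__name__)

__all__ = [
    "AnRNAPCConfig",
    "DEFAULT_ANRNAPC_CONFIG",
    "CATEGORY_NONE",
    "CATEGORY_OTHER",
    "classify_rnapc",
    "classify_outcome",
    "frequency_table",
    "frequency_frame",
    "mutator_summary",
]

CATEGORY_OTHER = "other_RNAPC"
CATEGORY_NONE = "none"

_CODING = frozenset({"nonsynonymous", "synonymous", "nonsense"})


@dataclass(frozen=True)
class AnRNAPCConfig:
    """Configured anRNAPC sites and the RNAPC gene set."""

    sites: tuple[tuple[str, int], ...] = (
        ("rpoB", 1272),
        ("rpoC", 334),
        ("rpoC", 428),
    )
    rnapc_genes: frozenset[str] = frozenset({"rpoA", "rpoB", "rpoC"})

    def __post_init__(self) -> None:
        genes = {g.lower() for g in self.rnapc_genes}
        for gene, aa in self.sites:
            if gene.lower() not in genes:
                raise ValueError(f"anRNAPC site gene {gene!r} not an RNAPC gene")
            if aa < 1:
                raise ValueError(f"residue number must be positive, got {aa}")

    def category_for_site(self, gene: str, aa: int) -> str:
        return f"anRNAPC_{gene}{aa}"

    @property
    def anrnapc_categories(self) -> tuple[str, ...]:
        return tuple(self.category_for_site(g, a) for g, a in self.sites)

    @property
    def categories(self) -> tuple[str, ...]:
        """All categories in display order."""
        return self.anrnapc_categories + (CATEGORY_OTHER, CATEGORY_NONE)


DEFAULT_ANRNAPC_CONFIG = AnRNAPCConfig()


def _is_rnapc(m: Mutation, cfg: AnRNAPCConfig) -> bool:
    return m.gene.lower() in {g.lower() for g in cfg.rnapc_genes}


def _anrnapc_hits(
    muts: Iterable[Mutation], cfg: AnRNAPCConfig
) -> list[tuple[tuple[str, int], Mutation]]:
    sites = {(g.lower(), a): (g, a) for g, a in cfg.sites}
    hits = []
    for m in muts:
        if m.mclass in _CODING and m.aa_position is not None:
            site = sites.get((m.gene.lower(), m.aa_position))
            if site is not None:
                hits.append((site, m))
    return hits


def classify_rnapc(clone: CloneGenotype, cfg: AnRNAPCConfig = DEFAULT_ANRNAPC_CONFIG) -> str:
    """Assign the clone's single RNAPC category.

    A coding mutation at a configured (gene, residue) site wins over any
    other RNAPC mutation; a clone hitting two configured sites (never
    observed experimentally) is reported under the lexicographically
    first site and logged.
    """
    hits = _anrnapc_hits(clone.mutations, cfg)
    if hits:
        sites = sorted({site for site, _ in hits})
        if len(sites) > 1:
            logger.warning(
                "%s: anRNAPC mutations at multiple sites %s; reporting %s",
                clone.clone_id, sites, sites[0],
            )
        return cfg.category_for_site(*sites[0])
    if any(_is_rnapc(m, cfg) for m in clone.mutations):
        return CATEGORY_OTHER
    return CATEGORY_NONE


def classify_outcome(
    founder: CloneGenotype,
    descendant: CloneGenotype,
    cfg: AnRNAPCConfig = DEFAULT_ANRNAPC_CONFIG,
) -> str:
    """Score a founder→descendant pair: reversion / compensation / retained.

    ``not_applicable`` when the founder carried no anRNAPC mutation.
    The caller asserts descent; only end-state genotypes are compared,
    so a compensatory mutation that preceded a later reversion is not
    distinguishable from plain reversion.
    """
    founder_hits = _anrnapc_hits(founder.mutations, cfg)
    if not founder_hits:
        return "not_applicable"
    desc_keys = descendant.mutation_keys
    if any(m.key not in desc_keys for _, m in founder_hits):
        return "reversion"
    founder_keys = founder.mutation_keys
    extra_rnapc = [
        m
        for m in descendant.mutations
        if _is_rnapc(m, cfg) and m.key not in founder_keys
    ]
    if extra_rnapc:
        return "compensation"
    return "retained"


def frequency_table(
    clones: Iterable[CloneGenotype],
    cfg: AnRNAPCConfig = DEFAULT_ANRNAPC_CONFIG,
) -> dict[int, dict[str, float]]:
    """Per-cycle category percentages over sequenced clones.

    Percentages within a cycle sum to 100.  Cycles with no clones are
    simply absent (the caller sees which cycles were reported).
    """
    by_cycle: dict[int, list[CloneGenotype]] = {}
    for c in clones:
        by_cycle.setdefault(c.cycle, []).append(c)
    table: dict[int, dict[str, float]] = {}
    for cycle in sorted(by_cycle):
        group = by_cycle[cycle]
        if not group:
            logger.warning("cycle %d has no clones; omitted", cycle)
            continue
        counts: dict[str, int] = {}
        for c in group:
            cat = classify_rnapc(c, cfg)
            counts[cat] = counts.get(cat, 0) + 1
        table[cycle] = {
            cat: 100.0 * n / len(group) for cat, n in sorted(counts.items())
        }
    return table


def frequency_frame(
    clones: Iterable[CloneGenotype],
    cfg: AnRNAPCConfig = DEFAULT_ANRNAPC_CONFIG,
) -> pd.DataFrame:
    """Tidy frame (cycle, category, n, percent) for stacked-bar plotting."""
    clones = list(clones)
    by_cycle: dict[int, list[str]] = {}
    for c in clones:
        by_cycle.setdefault(c.cycle, []).append(classify_rnapc(c, cfg))
    rows = []
    for cycle in sorted(by_cycle):
        cats = by_cycle[cycle]
        for cat in cfg.categories:
            n = cats.count(cat)
            if n:
                rows.append(
                    {
                        "cycle": cycle,
                        "category": cat,
                        "n": n,
                        "percent": 100.0 * n / len(cats),
                    }
                )
    return pd.DataFrame(rows, columns=["cycle", "category", "n", "percent"])


def mutator_summary(clones: Iterable[CloneGenotype]) -> dict[int, float]:
    """Fraction of mutator clones per dilution cycle."""
    by_cycle: dict[int, list[bool]] = {}
    for c in clones:
        by_cycle.setdefault(c.cycle, []).append(c.mutator)
    return {
        cycle: sum(flags) / len(flags)
        for cycle, flags in sorted(by_cycle.items())
        if flags
    }
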