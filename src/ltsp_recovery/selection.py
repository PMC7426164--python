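"""Fractional site counting, dN/dS, and NS/S enrichment testing.

Each position of a sense codon contributes fractionally to the counts
of nonsynonymous and synonymous sites according to the fraction of its
three possible single-nucleotide substitutions that change, or
preserve, the encoded amino acid: the third position of a four-fold
degenerate codon contributes a full synonymous site; the third position
of a two-fold degenerate codon contributes 1/3 synonymous and 2/3
nonsynonymous.  Summed over all codons of all coding sequences this
yields the genome-wide fractional site counts N (nonsynonymous) and S
(synonymous).

dN/dS for a set of observed new mutations with n nonsynonymous and s
synonymous members is the ratio of per-site rates

    dN/dS = (n / N) / (s / S),

undefined (reported as None / "N/A") when s = 0.  Departure from the
neutral expectation n : s = N : S is tested with a two-category
chi-squared goodness-of-fit test on 1 degree of freedom.

Substitutions that create a stop codon are counted as nonsynonymous by
default (``stop_as_ns``), making each codon contribute exactly 3 sites
in total; ``exclude_stop_targets`` drops them from the denominator for
sensitivity analysis.  The genetic code defaults to the bacterial
table (NCBI translation table 11).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.stats import chi2

__all__ = [
    "CodonSiteContribution",
    "SiteCounts",
    "DnDsResult",
    "codon_site_contributions",
    "site_counts",
    "site_counts_from_fasta",
    "site_counts_from_codon_usage",
    "load_k12_codon_usage",
    "dnds",
    "chi_square_enrichment",
    "dnds_result",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CodonSiteContribution:
    """Per-position (nonsynonymous, synonymous) site fractions of one codon."""

    codon: str
    per_position: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    @property
    def n_ns(self) -> float:
        return sum(p[0] for p in self.per_position)

    @property
    def n_syn(self) -> float:
        return sum(p[1] for p in self.per_position)


@dataclass(frozen=True)
class SiteCounts:
    """Genome-wide fractional counts of nonsynonymous and synonymous sites."""

    n_ns_sites: float
    n_syn_sites: float

    def __post_init__(self) -> None:
        if self.n_ns_sites < 0 or self.n_syn_sites < 0:
            raise ValueError("site counts must be non-negative")

    @property
    def ns_fraction(self) -> float:
        return self.n_ns_sites / (self.n_ns_sites + self.n_syn_sites)

    @property
    def ratio(self) -> float:
        """Nonsynonymous:synonymous site ratio N/S."""
        return self.n_ns_sites / self.n_syn_sites


@dataclass(frozen=True)
class DnDsResult:
    """Observed NS/S counts, dN/dS (None when undefined), and the χ² test."""

    n_ns_mut: int
    n_syn_mut: int
    dnds: Optional[float]
    chi2_stat: float
    p_value: float


def _codon_table(code: int = 11):
    return unambiguous_dna_by_id[code]


def codon_site_contributions(
    codon: str, code: int = 11, stop_policy: str = "stop_as_ns"
) -> CodonSiteContribution:
    """Fractional NS/S site contributions of one sense codon.

    For each position, the three possible substitutions are enumerated;
    the synonymous fraction is the share preserving the amino acid.
    Under ``stop_as_ns`` substitutions to a stop codon count as
    nonsynonymous and each position contributes exactly 1 site; under
    ``exclude_stop_targets`` they are dropped and the position's total
    can be below 1.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    if stop_policy not in {"stop_as_ns", "exclude_stop_targets"}:
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    table = _codon_table(code)
    if codon in table.stop_codons:
        raise ValueError(f"stop codon {codon} has no amino-acid site contribution")
    aa = table.forward_table[codon]
    per_position = []
    for i in range(3):
        syn = ns = 0
        targets = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if mutant in table.stop_codons:
                if stop_policy == "stop_as_ns":
                    ns += 1
                    targets += 1
                continue
            targets += 1
            if table.forward_table[mutant] == aa:
                syn += 1
            else:
                ns += 1
        if targets == 0:
            per_position.append((0.0, 0.0))
        else:
            per_position.append((ns / 3, syn / 3) if stop_policy == "stop_as_ns"
                                else (ns / targets, syn / targets))
    return CodonSiteContribution(codon=codon, per_position=tuple(per_position))


def site_counts(
    cds_set: Iterable[str],
    code: int = 11,
    stop_policy: str = "stop_as_ns",
    on_internal_stop: str = "error",
) -> SiteCounts:
    """Sum fractional site contributions over a set of coding sequences.

    Each CDS must have length divisible by 3; a terminal stop codon is
    excluded from counting.  Internal stop codons raise by default or
    skip the record with ``on_internal_stop="skip"``.
    """
    table = _codon_table(code)
    stops = set(table.stop_codons)
    cache: dict[str, tuple[float, float]] = {}
    n_ns = n_syn = 0.0
    n_records = 0
    for idx, cds in enumerate(cds_set):
        seq = str(cds).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            if on_internal_stop == "skip":
                continue
            raise ValueError(f"CDS #{idx}: length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        if any(c in stops for c in codons):
            if on_internal_stop == "skip":
                continue
            raise ValueError(f"CDS #{idx}: internal stop codon")
        for c in codons:
            if c not in cache:
                contrib = codon_site_contributions(c, code=code, stop_policy=stop_policy)
                cache[c] = (contrib.n_ns, contrib.n_syn)
            ns, syn = cache[c]
            n_ns += ns
            n_syn += syn
        n_records += 1
    if n_records == 0:
        raise ValueError("no usable coding sequences")
    return SiteCounts(n_ns_sites=n_ns, n_syn_sites=n_syn)


def site_counts_from_fasta(
    path, code: int = 11, stop_policy: str = "stop_as_ns",
    on_internal_stop: str = "error",
) -> SiteCounts:
    """Site counts over a multi-record FASTA of coding sequences."""
    seqs = (str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
    return site_counts(
        seqs, code=code, stop_policy=stop_policy, on_internal_stop=on_internal_stop
    )


def load_k12_codon_usage() -> dict[str, float]:
    """Published codon-usage composition of E. coli K-12 MG1655 CDSs.

    Returns per-1000-codon frequencies for the 61 sense codons of the
    bacterial code.  Fractional site counts over a CDS set depend only
    on its codon composition, so this table determines the genome-wide
    NS:S site ratio without the full sequence set.
    """
    text = (
        resources.files("ltsp_recovery")
        .joinpath("data/ecoli_k12_codon_usage.tsv")
        .read_text()
    )
    usage = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("codon\t"):
            continue
        codon, freq = line.split("\t")
        usage[codon] = float(freq)
    return usage


def site_counts_from_codon_usage(
    usage: dict[str, float], code: int = 11, stop_policy: str = "stop_as_ns"
) -> SiteCounts:
    """Usage-weighted site counts: Σ weight(codon) × contribution(codon)."""
    n_ns = n_syn = 0.0
    for codon, weight in usage.items():
        contrib = codon_site_contributions(codon, code=code, stop_policy=stop_policy)
        n_ns += weight * contrib.n_ns
        n_syn += weight * contrib.n_syn
    return SiteCounts(n_ns_sites=n_ns, n_syn_sites=n_syn)


def dnds(n_ns_mut: int, n_syn_mut: int, sites: SiteCounts) -> Optional[float]:
    """Ratio of per-site rates (n/N)/(s/S); None (N/A) when s = 0."""
    if n_ns_mut < 0 or n_syn_mut < 0:
        raise ValueError("mutation counts must be non-negative")
    if n_syn_mut == 0:
        return None
    return (n_ns_mut / sites.n_ns_sites) / (n_syn_mut / sites.n_syn_sites)


def chi_square_enrichment(
    n_ns_mut: int, n_syn_mut: int, sites: SiteCounts
) -> tuple[float, float]:
    """χ² goodness-of-fit of observed NS/S counts to the site proportions.

    Expected counts split the observed total by N/(N+S) and S/(N+S);
    the statistic Σ(obs−exp)²/exp has 1 degree of freedom, upper-tail
    p-value.  No continuity correction is applied.
    """
    total = n_ns_mut + n_syn_mut
    if total <= 0:
        raise ValueError("need at least one classified mutation")
    exp_ns = total * sites.ns_fraction
    exp_syn = total - exp_ns
    stat = (n_ns_mut - exp_ns) ** 2 / exp_ns + (n_syn_mut - exp_syn) ** 2 / exp_syn
    p = float(chi2.sf(stat, df=1))
    return float(stat), p


def dnds_result(n_ns_mut: int, n_syn_mut: int, sites: SiteCounts) -> DnDsResult:
    """Bundle dN/dS with its enrichment test for one mutation set."""
    stat, p = chi_square_enrichment(n_ns_mut, n_syn_mut, sites)
    return DnDsResult(
        n_ns_mut=n_ns_mut,
        n_syn_mut=n_syn_mut,
        dnds=dnds(n_ns_mut, n_syn_mut, sites),
        chi2_stat=stat,
        p_value=p,
    )
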