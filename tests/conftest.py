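"""Shared fixtures: reconstruction-style clone sets and site counts.

The clone fixtures rebuild, at small scale, the structure of the
experimental samples: a diverse day-127 population (9 of 11 clones
carrying an anRNAPC allele), its day-10 serial-dilution sample with the
allele gone, and founder→descendant lineages recovering through
compensation, reversion, or neither.
"""

from pathlib import Path

import pytest

from ltsp_recovery import selection as sel
from ltsp_recovery.mutations import CloneGenotype, Mutation

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def k12_usage() -> dict[str, float]:
    return sel.load_k12_codon_usage()


@pytest.fixture(scope="session")
def k12_sites(k12_usage) -> sel.SiteCounts:
    """Genome-composition-weighted fractional site counts."""
    return sel.site_counts_from_codon_usage(k12_usage)


def _clone(clone_id, cycle, muts, mutator=False, population="2", day=127):
    return CloneGenotype(
        clone_id=clone_id,
        population=population,
        day=day,
        cycle=cycle,
        mutations=frozenset(muts),
        mutator=mutator,
    )


def _snp(pos, gene, aa, mclass="nonsynonymous", ref="C", alt="T"):
    return Mutation(pos, ref, alt, gene, mclass, aa_position=aa)


ANRNAPC_RPOB1272 = _snp(4_181_245, "rpoB", 1272)
ANRNAPC_RPOC334 = _snp(4_186_700, "rpoC", 334)
ANRNAPC_RPOC428 = _snp(4_186_982, "rpoC", 428)
COMP_RPOC1075 = _snp(4_188_923, "rpoC", 1075, ref="T", alt="G")
COMP_RPOB546 = _snp(4_179_100, "rpoB", 546, ref="A", alt="C")


def _passengers(start_pos, n, mclass="synonymous"):
    aa = 10 if mclass in {"nonsynonymous", "synonymous", "nonsense"} else None
    return [
        Mutation(start_pos + i * 137, "G", "A", f"y{start_pos + i}", mclass, aa_position=aa)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def pop2_day127_clones() -> list[CloneGenotype]:
    """Eleven day-127 clones: 3+3+3 across the anRNAPC sites, 2 without."""
    clones = []
    sites = [ANRNAPC_RPOB1272, ANRNAPC_RPOC334, ANRNAPC_RPOC428]
    k = 0
    for i, site in enumerate(sites):
        for j in range(3):
            k += 1
            muts = [site] + _passengers(10_000 + 1_000 * k, 3 + j)
            clones.append(
                _clone(f"2_{k}", 0, muts, mutator=(k in {2, 9}))
            )
    # the two near-ancestral clones: four mutations, no RNAPC hit
    for cid in ("2_5x", "2_6x"):
        k += 1
        clones.append(_clone(cid, 0, _passengers(200_000 + 1_000 * k, 4)))
    return clones


@pytest.fixture(scope="session")
def pop2_day10_clones() -> list[CloneGenotype]:
    """Ten cycle-10 clones, anRNAPC allele no longer observed."""
    return [
        _clone(f"2_d10_{i}", 10, _passengers(400_000 + 1_000 * i, 4))
        for i in range(1, 11)
    ]


@pytest.fixture(scope="session")
def clone21_lineage() -> tuple[CloneGenotype, list[CloneGenotype]]:
    """Nonmutator founder with an anRNAPC allele; ten compensated descendants.

    Every descendant retains the founder allele and adds one secondary
    RNAPC mutation; two carry one extra passenger (new-mutation counts
    of 1–2 per descendant).
    """
    founder_muts = [ANRNAPC_RPOB1272] + _passengers(50_000, 7)
    founder = _clone("2_1", 0, founder_muts)
    descendants = []
    for i in range(1, 11):
        comp = COMP_RPOC1075 if i % 2 else COMP_RPOB546
        muts = list(founder_muts) + [comp]
        if i <= 2:
            muts += _passengers(600_000 + 1_000 * i, 1)
        descendants.append(_clone(f"2_1_d{i}", 16, muts))
    return founder, descendants


@pytest.fixture(scope="session")
def clone45_lineage() -> tuple[CloneGenotype, list[CloneGenotype]]:
    """Mutator founder whose descendants lost the anRNAPC allele (reversion)."""
    founder_muts = [ANRNAPC_RPOC334] + _passengers(70_000, 10)
    founder = _clone("4_5", 0, founder_muts, mutator=True, population="4")
    descendants = [
        _clone(
            f"4_5_d{i}",
            16,
            [m for m in founder_muts if m is not ANRNAPC_RPOC334]
            + _passengers(700_000 + 2_000 * i, 5),
            mutator=True,
            population="4",
        )
        for i in range(1, 4)
    ]
    return founder, descendants


@pytest.fixture(scope="session")
def clone26_lineage() -> tuple[CloneGenotype, list[CloneGenotype]]:
    """Founder without any RNAPC mutation: outcomes are not applicable."""
    founder = _clone("2_6", 0, _passengers(90_000, 4))
    descendants = [
        _clone(
            f"2_6_d{i}",
            16,
            _passengers(90_000, 4) + _passengers(800_000 + 1_000 * i, 2 + i),
        )
        for i in range(1, 3)
    ]
    return founder, descendants
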