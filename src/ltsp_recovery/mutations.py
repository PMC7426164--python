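"""Clone genotypes and mutation tables.

A clone's genotype is the set of mutations called against the ancestral
reference (E. coli K-12 MG1655, NC_000913, for the experiments this
package models).  Mutation identity is the (position, alt_allele) pair:
two calls at the same coordinate with the same derived allele are the
same mutation regardless of annotation strings, which is also what makes
a reversion detectable — the ancestral clone's derived allele disappears
from its descendant.

"New" mutations are defined in two ways, matching how serial-dilution
descendants are scored: against a single ancestral clone (set
difference), or against a population's sequencing history (every
mutation ever seen in any sequenced clone of that population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MUTATION_CLASSES",
    "DEFAULT_MUTATOR_GENES",
    "Mutation",
    "CloneGenotype",
    "PopulationHistory",
    "new_mutations_vs_ancestor",
    "new_mutations_vs_history",
    "class_counts",
    "read_mutation_table",
    "write_mutation_table",
    "flag_mutators",
]

MUTATION_CLASSES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "nonsense",
        "frameshift",
        "noncoding",
        "intergenic",
        "large_deletion",
        "new_junction",
    }
)

#: Mismatch-repair genes used by :func:`flag_mutators`; a clone with a
#: mutation in any of these is flagged a mutator.  Curated metadata in
#: input tables takes precedence; the gene list is configuration, not a
#: claim that these are the only mutator loci.
DEFAULT_MUTATOR_GENES = frozenset({"mutS", "mutL", "mutH", "uvrD"})

#: Fallback class for annotation strings the readers do not recognise.
FALLBACK_CLASS = "noncoding"

_CODING_CLASSES = frozenset({"nonsynonymous", "synonymous", "nonsense"})


@dataclass(frozen=True)
class Mutation:
    """One called mutation on the reference genome (1-based coordinates)."""

    position: int
    ref_allele: str
    alt_allele: str
    gene: str
    mclass: str
    aa_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if self.aa_position is not None and self.mclass not in _CODING_CLASSES:
            raise ValueError(
                f"aa_position given for non-coding class {self.mclass!r}"
            )

    @property
    def key(self) -> tuple[int, str]:
        """Identity key: (position, alt_allele)."""
        return (self.position, self.alt_allele)


@dataclass(frozen=True)
class CloneGenotype:
    """A sequenced clone: its mutation set plus sampling metadata.

    ``cycle`` is the serial-dilution cycle the clone was sampled at
    (0 for isolates taken straight from the long-term-stationary-phase
    flask); ``day`` is the LTSP day of the founding sample.
    """

    clone_id: str
    population: str
    day: int
    cycle: int
    mutations: frozenset[Mutation]
    mutator: bool = False
    reference: str = "NC_000913"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", frozenset(self.mutations))
        keys = [m.key for m in self.mutations]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"{self.clone_id}: duplicate (position, alt_allele) pairs"
            )

    @property
    def mutation_keys(self) -> frozenset[tuple[int, str]]:
        return frozenset(m.key for m in self.mutations)


@dataclass(frozen=True)
class PopulationHistory:
    """Union of all mutations seen in any sequenced clone of a population."""

    population: str
    observed_mutations: frozenset[Mutation]

    @classmethod
    def from_clones(cls, clones: Iterable[CloneGenotype]) -> "PopulationHistory":
        clones = list(clones)
        pops = {c.population for c in clones}
        if len(pops) != 1:
            raise ValueError(f"clones span multiple populations: {sorted(pops)}")
        muts: set[Mutation] = set()
        for c in clones:
            muts |= c.mutations
        return cls(population=pops.pop(), observed_mutations=frozenset(muts))

    @property
    def observed_keys(self) -> frozenset[tuple[int, str]]:
        return frozenset(m.key for m in self.observed_mutations)


def new_mutations_vs_ancestor(
    descendant: CloneGenotype, ancestor: CloneGenotype
) -> frozenset[Mutation]:
    """Mutations in the descendant absent from the ancestor.

    Keyed by (position, alt_allele).  An ancestral mutation missing from
    the descendant is NOT reported here — that is a reversion, scored by
    the outcome classifier.
    """
    if descendant.reference != ancestor.reference:
        raise ValueError(
            f"reference mismatch: {descendant.reference!r} vs {ancestor.reference!r}"
        )
    anc_keys = ancestor.mutation_keys
    return frozenset(m for m in descendant.mutations if m.key not in anc_keys)


def new_mutations_vs_history(
    clone: CloneGenotype, history: PopulationHistory
) -> frozenset[Mutation]:
    """Mutations never seen in the population's sequencing history."""
    if clone.population != history.population:
        raise ValueError(
            f"population mismatch: clone {clone.population!r} vs "
            f"history {history.population!r}"
        )
    seen = history.observed_keys
    return frozenset(m for m in clone.mutations if m.key not in seen)


def class_counts(muts: Iterable[Mutation]) -> dict[str, int]:
    """Count mutations per class; classes partition the set."""
    counts = {cls: 0 for cls in sorted(MUTATION_CLASSES)}
    for m in muts:
        counts[m.mclass] += 1
    return counts


# ---------------------------------------------------------------------------
# Readers / writers

_TSV_COLUMNS = [
    "clone_id",
    "population",
    "day",
    "cycle",
    "position",
    "ref",
    "alt",
    "gene",
    "aa_position",
    "mclass",
    "mutator",
]


def _normalise_class(raw: str, where: str) -> str:
    cls = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    if cls in MUTATION_CLASSES:
        return cls
    logger.warning("%s: unknown mutation class %r, recorded as %s", where, raw, FALLBACK_CLASS)
    return FALLBACK_CLASS


def read_mutation_table(path, dialect: str = "tsv") -> list[CloneGenotype]:
    """Read clone genotypes from a mutation table.

    dialect "tsv": the package's tab-separated format (one row per
    mutation, columns clone_id, population, day, cycle, position, ref,
    alt, gene, aa_position, mclass, mutator).  dialect "genomediff": a
    Breseq GenomeDiff file; one file describes one clone.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "genomediff":
        return [_read_genomediff(path)]
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path) -> list[CloneGenotype]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty mutation table") from exc
    missing = [c for c in _TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    clones: list[CloneGenotype] = []
    for (clone_id, population, day, cycle, mutator), grp in frame.groupby(
        ["clone_id", "population", "day", "cycle", "mutator"], sort=False
    ):
        muts = set()
        for idx, row in grp.iterrows():
            where = f"{path}:{idx + 2}"
            try:
                aa = row["aa_position"]
                aa_pos = None if pd.isna(aa) or str(aa) == "" else int(float(aa))
                muts.add(
                    Mutation(
                        position=int(row["position"]),
                        ref_allele=str(row["ref"]),
                        alt_allele=str(row["alt"]),
                        gene=str(row["gene"]),
                        mclass=_normalise_class(row["mclass"], where),
                        aa_position=aa_pos,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{where}: malformed mutation row: {exc}") from exc
        clones.append(
            CloneGenotype(
                clone_id=str(clone_id),
                population=str(population),
                day=int(day),
                cycle=int(cycle),
                mutations=frozenset(muts),
                mutator=str(mutator).strip().lower() in {"true", "1", "yes"},
            )
        )
    return clones


def write_mutation_table(clones: Iterable[CloneGenotype], path) -> None:
    """Write clone genotypes in the package's TSV dialect."""
    rows = []
    for c in clones:
        for m in sorted(c.mutations, key=lambda m: m.key):
            rows.append(
                {
                    "clone_id": c.clone_id,
                    "population": c.population,
                    "day": c.day,
                    "cycle": c.cycle,
                    "position": m.position,
                    "ref": m.ref_allele,
                    "alt": m.alt_allele,
                    "gene": m.gene,
                    "aa_position": "" if m.aa_position is None else m.aa_position,
                    "mclass": m.mclass,
                    "mutator": c.mutator,
                }
            )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# Breseq GenomeDiff mutation-line field layouts (evidence-free prefix).
_GD_FIXED = {
    "SNP": ("seq_id", "position", "new_seq"),
    "INS": ("seq_id", "position", "new_seq"),
    "DEL": ("seq_id", "position", "size"),
    "MOB": ("seq_id", "position", "repeat_name", "strand", "duplication_size"),
    "JC": (
        "side_1_seq_id",
        "side_1_position",
        "side_1_strand",
        "side_2_seq_id",
        "side_2_position",
        "side_2_strand",
        "overlap",
    ),
}

_GD_SNP_CLASS = {
    "nonsynonymous": "nonsynonymous",
    "synonymous": "synonymous",
    "nonsense": "nonsense",
    "noncoding": "noncoding",
    "intergenic": "intergenic",
    "pseudogene": "noncoding",
}


def _read_genomediff(path) -> CloneGenotype:
    """Minimal reader for Breseq GenomeDiff mutation lines (SNP/INS/DEL/MOB/JC).

    SNP classes come from the ``snp_type`` key; INS/DEL within a gene are
    recorded as frameshift, DEL without a gene as large_deletion; MOB and
    JC as new_junction.  Evidence lines (two-letter types) are ignored.
    """
    path = Path(path)
    title = path.stem
    meta: dict[str, str] = {}
    muts: set[Mutation] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#="):
                    parts = line[2:].split(None, 1)
                    if len(parts) == 2:
                        meta[parts[0].strip()] = parts[1].strip()
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind not in _GD_FIXED and len(kind) == 2:
                continue  # evidence line (RA, MC, UN ...)
            if kind not in _GD_FIXED:
                logger.warning("%s:%d: unsupported GD record %r, skipped", path, lineno, kind)
                continue
            fixed = _GD_FIXED[kind]
            if len(fields) < 3 + len(fixed):
                raise ValueError(f"{path}:{lineno}: truncated {kind} record")
            rec = dict(zip(fixed, fields[3 : 3 + len(fixed)]))
            kv = {}
            for extra in fields[3 + len(fixed):]:
                if "=" in extra:
                    k, _, v = extra.partition("=")
                    kv[k] = v
            gene = kv.get("gene_name", "intergenic")
            aa_pos = kv.get("aa_position")
            try:
                if kind == "SNP":
                    raw = kv.get("snp_type", "")
                    mclass = _GD_SNP_CLASS.get(raw.lower())
                    if mclass is None:
                        logger.warning(
                            "%s:%d: unknown snp_type %r, recorded as %s",
                            path, lineno, raw, FALLBACK_CLASS,
                        )
                        mclass = FALLBACK_CLASS
                    muts.add(
                        Mutation(
                            position=int(rec["position"]),
                            ref_allele=kv.get("ref_seq", "N"),
                            alt_allele=rec["new_seq"],
                            gene=gene,
                            mclass=mclass,
                            aa_position=(
                                int(aa_pos)
                                if aa_pos and mclass in _CODING_CLASSES
                                else None
                            ),
                        )
                    )
                elif kind == "INS":
                    muts.add(
                        Mutation(
                            position=int(rec["position"]),
                            ref_allele="",
                            alt_allele=f"+{rec['new_seq']}",
                            gene=gene,
                            mclass="frameshift" if "gene_name" in kv else "intergenic",
                        )
                    )
                elif kind == "DEL":
                    muts.add(
                        Mutation(
                            position=int(rec["position"]),
                            ref_allele="",
                            alt_allele=f"-{rec['size']}",
                            gene=gene,
                            mclass="frameshift" if "gene_name" in kv else "large_deletion",
                        )
                    )
                elif kind == "MOB":
                    muts.add(
                        Mutation(
                            position=int(rec["position"]),
                            ref_allele="",
                            alt_allele=f"MOB:{rec['repeat_name']}",
                            gene=gene,
                            mclass="new_junction",
                        )
                    )
                else:  # JC
                    muts.add(
                        Mutation(
                            position=int(rec["side_1_position"]),
                            ref_allele="",
                            alt_allele=(
                                f"JC:{rec['side_2_seq_id']}:{rec['side_2_position']}"
                            ),
                            gene=gene,
                            mclass="new_junction",
                        )
                    )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {kind} record: {exc}") from exc
    return CloneGenotype(
        clone_id=meta.get("TITLE", title),
        population=meta.get("POPULATION", "unknown"),
        day=int(meta.get("DAY", 0)),
        cycle=int(meta.get("CYCLE", 0)),
        mutations=frozenset(muts),
        mutator=meta.get("MUTATOR", "").strip().lower() in {"true", "1", "yes"},
    )


def flag_mutators(
    clones: Iterable[CloneGenotype],
    mutator_genes: frozenset[str] = DEFAULT_MUTATOR_GENES,
) -> list[CloneGenotype]:
    """Return copies with ``mutator`` set where a mismatch-repair gene is hit.

    Clones already flagged stay flagged (curated metadata wins).
    """
    genes = {g.lower() for g in mutator_genes}
    out = []
    for c in clones:
        hit = any(m.gene.lower() in genes for m in c.mutations)
        if hit and not c.mutator:
            c = CloneGenotype(
                clone_id=c.clone_id,
                population=c.population,
                day=c.day,
                cycle=c.cycle,
                mutations=c.mutations,
                mutator=True,
                reference=c.reference,
            )
        out.append(c)
    return out
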