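"""Serial-dilution evolution simulator and synthetic-data emitters.

Models the daily-transfer regime of a recovery experiment: a population
regrows in fresh medium, is sampled through a 1:100 bottleneck, and
repeats for a configured number of cycles.  A 1:100 dilution allows
log2(100) ≈ 6.64 generations of regrowth per cycle, so growth-rate
differences between genotypes compound quickly: with deterministic
within-cycle growth the log2 abundance odds between two genotypes
change by exactly g·(r1−r2)/max_rate per cycle.

Growth within a cycle is deterministic (each genotype doubles in
proportion to its relative rate, the fastest genotype completing
exactly g doublings); stochasticity enters at the bottleneck
(multinomial sampling of ``bottleneck_n`` cells) and through rare
mutation events.  Mutation moves cells from genotypes carrying the
costly anRNAPC allele either to a reverted genotype (allele lost,
wild-type rate restored) or to a compensated genotype (allele retained,
cost reduced by a configured fraction); mutator genotypes scale both
rates by ``mutator_factor``.

The module also fabricates the synthetic inputs the analysis modules
consume: plate-reader OD curves (logistic growth with lag and Gaussian
noise), clone mutation tables with founder-defining and passenger
mutations, and a synthetic coding-sequence complement matching a given
codon-usage composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .growth import ODCurve
from .mutations import CloneGenotype, Mutation

__all__ = [
    "GenotypeSpec",
    "SimulationConfig",
    "PopulationState",
    "SimulationResult",
    "grow_cycle",
    "dilute",
    "mutate",
    "run_experiment",
    "emit_clone_sample",
    "emit_od_curves",
    "write_plate_csv",
    "trajectory_frame",
    "synthetic_cds_complement",
]

#: Length of the reference genome positions are fabricated on (E. coli
#: K-12 MG1655 scale).
GENOME_LENGTH = 4_641_652

#: Default anRNAPC site fabricated for allele-carrying genotypes.
_ANRNAPC_SITE = ("rpoB", 1272)
#: Compensatory RNAPC sites observed experimentally.
_COMP_SITES = (("rpoC", 1075), ("rpoB", 546))


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype in the simulated population.

    ``relative_rate`` is the exponential growth rate relative to wild
    type (1.0); the anRNAPC allele costs ~20%, i.e. rate 0.8.
    ``base_mutation_load`` is the expected number of passenger mutations
    fabricated per sampled clone.
    """

    genotype_id: str
    relative_rate: float
    mutator: bool = False
    carries_anrnapc: bool = False
    base_mutation_load: float = 0.0
    parent_id: Optional[str] = None
    derivation: Optional[str] = None  # "reversion" | "compensation"

    def __post_init__(self) -> None:
        if self.relative_rate <= 0:
            raise ValueError(f"{self.genotype_id}: relative_rate must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Transfer-regime and mutation parameters.

    ``generations_per_cycle`` defaults to log2(dilution_factor): the
    regrowth needed to restore pre-dilution density.  Mutation rates are
    per genome per generation; defaults are illustrative, not estimates
    (per-base rates of order 1e-10 with a single reversion target and a
    handful of compensatory targets).  ``bottleneck_n`` is scaled down
    from the ~1e8 cells a real 1:100 transfer of saturated LB carries.
    """

    dilution_factor: float = 100.0
    generations_per_cycle: Optional[float] = None
    bottleneck_n: int = 1_000_000
    cycles: int = 16
    mu_reversion: float = 1e-10
    mu_compensation: float = 4e-10
    mutator_factor: float = 100.0
    compensation_rate_recovery: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for name in ("mu_reversion", "mu_compensation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.compensation_rate_recovery <= 1.0:
            raise ValueError("compensation_rate_recovery must be in [0, 1]")

    @property
    def g(self) -> float:
        """Generations of regrowth per cycle."""
        if self.generations_per_cycle is not None:
            return self.generations_per_cycle
        return math.log2(self.dilution_factor)


@dataclass(frozen=True)
class PopulationState:
    """Genotype abundances at one point of the experiment.

    Post-dilution counts are integers summing to ``bottleneck_n``;
    post-growth abundances are real-valued.
    """

    cycle: int
    counts: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative abundance")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            raise ValueError("empty population has no frequencies")
        return {g: c / tot for g, c in self.counts.items()}


@dataclass
class SimulationResult:
    """Trajectory of post-dilution states plus per-cycle mean rates.

    ``states[0]`` is the founding bottleneck (cycle 0);
    ``mean_relative_rate[k]`` is the abundance-weighted mean relative
    growth rate of the population as it regrew during cycle k+1.
    """

    states: list[PopulationState]
    mean_relative_rate: list[float]
    specs: dict[str, GenotypeSpec]


def _max_rate(state: PopulationState, specs: Mapping[str, GenotypeSpec]) -> float:
    present = [specs[g].relative_rate for g, c in state.counts.items() if c > 0]
    if not present:
        raise ValueError("empty population")
    return max(present)


def grow_cycle(
    state: PopulationState,
    specs: Mapping[str, GenotypeSpec],
    cfg: SimulationConfig,
) -> PopulationState:
    """Deterministic regrowth: genotype i multiplies by 2^(g·r_i/max_r)."""
    if state.total <= 0:
        raise ValueError("cannot grow an empty population")
    max_r = _max_rate(state, specs)
    grown = {
        gid: c * 2.0 ** (cfg.g * specs[gid].relative_rate / max_r)
        for gid, c in state.counts.items()
        if c > 0
    }
    return PopulationState(cycle=state.cycle, counts=grown)


def dilute(
    state: PopulationState, cfg: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Multinomial bottleneck of ``bottleneck_n`` cells."""
    if state.total <= 0:
        raise ValueError("cannot dilute an empty population")
    gids = sorted(state.counts)
    weights = np.array([state.counts[g] for g in gids], dtype=float)
    probs = weights / weights.sum()
    draws = rng.multinomial(cfg.bottleneck_n, probs)
    counts = {g: int(n) for g, n in zip(gids, draws) if n > 0}
    return PopulationState(cycle=state.cycle + 1, counts=counts)


def _derived(
    spec: GenotypeSpec, kind: str, cfg: SimulationConfig
) -> GenotypeSpec:
    if kind == "reversion":
        return GenotypeSpec(
            genotype_id=f"{spec.genotype_id}::rev",
            relative_rate=1.0,
            mutator=spec.mutator,
            carries_anrnapc=False,
            base_mutation_load=spec.base_mutation_load,
            parent_id=spec.genotype_id,
            derivation="reversion",
        )
    cost = 1.0 - spec.relative_rate
    return GenotypeSpec(
        genotype_id=f"{spec.genotype_id}::comp",
        relative_rate=spec.relative_rate + cost * cfg.compensation_rate_recovery,
        mutator=spec.mutator,
        carries_anrnapc=True,
        base_mutation_load=spec.base_mutation_load,
        parent_id=spec.genotype_id,
        derivation="compensation",
    )


def mutate(
    state: PopulationState,
    specs: Mapping[str, GenotypeSpec],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PopulationState, dict[str, GenotypeSpec]]:
    """Apply reversion and compensation events at the cycle boundary.

    Expected events per eligible genotype are cells × g × mu (times
    ``mutator_factor`` for mutators), Poisson-drawn and capped at the
    genotype's abundance; affected cells move to the derived genotype.
    Lineage detail below frequency scale is not tracked.
    """
    specs = dict(specs)
    counts = dict(state.counts)
    for gid in sorted(state.counts):
        spec = specs[gid]
        if not spec.carries_anrnapc:
            continue
        cells = counts[gid]
        if cells <= 0:
            continue
        factor = cfg.mutator_factor if spec.mutator else 1.0
        for kind, mu in (
            ("reversion", cfg.mu_reversion),
            ("compensation", cfg.mu_compensation),
        ):
            if mu <= 0:
                continue
            expected = cells * cfg.g * mu * factor
            n_events = min(int(rng.poisson(expected)), int(counts[gid]))
            if n_events <= 0:
                continue
            child = _derived(spec, kind, cfg)
            if child.genotype_id not in specs:
                specs[child.genotype_id] = child
            counts[gid] -= n_events
            counts[child.genotype_id] = counts.get(child.genotype_id, 0) + n_events
    return PopulationState(cycle=state.cycle, counts=counts), specs


def run_experiment(
    initial: PopulationState | Mapping[str, float],
    specs: Iterable[GenotypeSpec],
    cfg: SimulationConfig,
) -> SimulationResult:
    """Iterate grow → mutate → dilute for ``cfg.cycles`` transfers.

    Reproducible for a given ``cfg.seed``.  Also records the
    abundance-weighted mean relative growth rate of each cycle's
    regrown population (1.0 = wild type).
    """
    spec_map = {s.genotype_id: s for s in specs}
    if not isinstance(initial, PopulationState):
        initial = PopulationState(cycle=0, counts=dict(initial))
    unknown = set(initial.counts) - set(spec_map)
    if unknown:
        raise ValueError(f"initial counts reference unknown genotypes: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    states = [initial]
    mean_rates: list[float] = []
    state = initial
    for _ in range(cfg.cycles):
        grown = grow_cycle(state, spec_map, cfg)
        grown, spec_map = mutate(grown, spec_map, cfg, rng)
        tot = grown.total
        mean_rates.append(
            sum(spec_map[g].relative_rate * c for g, c in grown.counts.items()) / tot
        )
        state = dilute(grown, cfg, rng)
        states.append(state)
    return SimulationResult(states=states, mean_relative_rate=mean_rates, specs=spec_map)


# ---------------------------------------------------------------------------
# Synthetic clone tables


def _fabricate_positions(rng: np.random.Generator, n: int, used: set[int]) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        pos = int(rng.integers(1, GENOME_LENGTH + 1))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _founder_mutation_sets(
    gids: Sequence[str],
    specs: Mapping[str, GenotypeSpec],
    rng: np.random.Generator,
    used_positions: set[int],
) -> dict[str, frozenset[Mutation]]:
    """Fabricate founder-defining mutation sets, respecting derivations.

    Base genotypes get an anRNAPC allele (if carried), a mismatch-repair
    mutation (if mutator) and a neutral marker; reverted descendants
    drop the anRNAPC allele, compensated ones add a secondary RNAPC
    mutation at an experimentally observed compensatory site.
    """
    sets: dict[str, frozenset[Mutation]] = {}

    def build(gid: str) -> frozenset[Mutation]:
        if gid in sets:
            return sets[gid]
        spec = specs[gid]
        if spec.parent_id is None:
            muts: set[Mutation] = set()
            if spec.carries_anrnapc:
                gene, aa = _ANRNAPC_SITE
                pos = _fabricate_positions(rng, 1, used_positions)[0]
                muts.add(
                    Mutation(pos, "C", "T", gene, "nonsynonymous", aa_position=aa)
                )
            if spec.mutator:
                pos = _fabricate_positions(rng, 1, used_positions)[0]
                muts.add(
                    Mutation(pos, "G", "A", "mutS", "nonsynonymous", aa_position=211)
                )
            pos = _fabricate_positions(rng, 1, used_positions)[0]
            muts.add(Mutation(pos, "A", "C", "marker", "synonymous", aa_position=10))
        else:
            parent = build(spec.parent_id)
            if spec.derivation == "reversion":
                muts = {
                    m
                    for m in parent
                    if not (m.gene, m.aa_position) == _ANRNAPC_SITE
                }
            else:  # compensation
                gene, aa = _COMP_SITES[
                    int(rng.integers(0, len(_COMP_SITES)))
                ]
                pos = _fabricate_positions(rng, 1, used_positions)[0]
                muts = set(parent) | {
                    Mutation(pos, "T", "G", gene, "nonsynonymous", aa_position=aa)
                }
        sets[gid] = frozenset(muts)
        return sets[gid]

    for gid in gids:
        build(gid)
    return sets


def emit_clone_sample(
    state: PopulationState,
    specs: Mapping[str, GenotypeSpec],
    n_clones: int,
    site_fractions: tuple[float, float],
    rng: np.random.Generator,
    population: str = "sim",
    day: int = 127,
) -> list[CloneGenotype]:
    """Sequence-like sample: draw clones by frequency, fabricate mutations.

    Each clone carries its genotype's founder-defining mutations plus
    Poisson(base_mutation_load) passenger point mutations whose
    nonsynonymous/synonymous classes are drawn proportional to
    ``site_fractions`` (ns, syn).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    freqs = state.frequencies
    gids = sorted(freqs)
    probs = np.array([freqs[g] for g in gids])
    drawn = rng.choice(len(gids), size=n_clones, p=probs)
    used_positions: set[int] = set()
    founder_sets = _founder_mutation_sets(
        [gids[i] for i in sorted(set(drawn))], specs, rng, used_positions
    )
    ns_f, syn_f = site_fractions
    p_ns = ns_f / (ns_f + syn_f)
    clones = []
    for k, idx in enumerate(drawn):
        gid = gids[idx]
        spec = specs[gid]
        muts = set(founder_sets[gid])
        n_pass = int(rng.poisson(spec.base_mutation_load))
        for pos in _fabricate_positions(rng, n_pass, used_positions):
            is_ns = rng.random() < p_ns
            muts.add(
                Mutation(
                    pos,
                    "G",
                    "T",
                    f"gene{pos % 4001}",
                    "nonsynonymous" if is_ns else "synonymous",
                    aa_position=1 + pos % 300,
                )
            )
        clones.append(
            CloneGenotype(
                clone_id=f"{population}_{state.cycle}_{k + 1}",
                population=population,
                day=day,
                cycle=state.cycle,
                mutations=frozenset(muts),
                mutator=spec.mutator,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# Synthetic OD curves


def emit_od_curves(
    specs: Iterable[GenotypeSpec],
    rng: np.random.Generator,
    wildtype_rate_per_min: float = 0.025,
    od0: float = 0.05,
    carrying_capacity: float = 1.4,
    lag_min: float = 60.0,
    noise_sd: float = 0.002,
    additive_sd: float = 0.0005,
    duration_min: float = 720.0,
    interval_min: float = 10.0,
    replicates: int = 1,
) -> list[ODCurve]:
    """Synthetic plate-reader wells: logistic growth with lag and noise.

    Intrinsic rate is relative_rate × wildtype_rate_per_min (default:
    wild type doubles every ~28 min in fresh LB).  Measurement noise
    has a component proportional to the signal (``noise_sd``, relative)
    and a small absolute floor (``additive_sd``, OD units); readings
    are clipped at 0.  An infinite ``carrying_capacity`` yields a pure
    exponential curve, useful for exact round-trip checks.  With
    ``replicates`` > 1, wells are named ``<genotype_id>.r<j>``.
    """
    times = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    t_eff = np.clip(times - lag_min, 0.0, None)
    K = carrying_capacity
    curves = []
    for spec in specs:
        r = spec.relative_rate * wildtype_rate_per_min
        if math.isinf(K):
            clean = od0 * np.exp(r * t_eff)
        else:
            clean = K / (1.0 + (K - od0) / od0 * np.exp(-r * t_eff))
        for j in range(replicates):
            od = clean
            if noise_sd > 0:
                od = od * (1.0 + rng.normal(0.0, noise_sd, size=od.shape))
            if additive_sd > 0:
                od = od + rng.normal(0.0, additive_sd, size=od.shape)
            od = np.clip(od, 0.0, None)
            sid = spec.genotype_id if replicates == 1 else f"{spec.genotype_id}.r{j}"
            curves.append(ODCurve(sample_id=sid, times=tuple(times), od=tuple(od)))
    return curves


def write_plate_csv(curves: Sequence[ODCurve], path) -> None:
    """Write curves as a plate CSV (time_min column + one column per well)."""
    if not curves:
        raise ValueError("no curves to write")
    times = curves[0].times
    for c in curves:
        if c.times != times:
            raise ValueError("all curves must share the time grid")
    frame = pd.DataFrame({"time_min": times})
    for c in curves:
        frame[c.sample_id] = c.od
    frame.to_csv(path, index=False)


def trajectory_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy trajectory (cycle, genotype_id, count, frequency)."""
    rows = []
    for state in result.states:
        tot = state.total
        for gid in sorted(state.counts):
            c = state.counts[gid]
            rows.append(
                {
                    "cycle": state.cycle,
                    "genotype_id": gid,
                    "count": c,
                    "frequency": c / tot,
                }
            )
    return pd.DataFrame(rows, columns=["cycle", "genotype_id", "count", "frequency"])


# ---------------------------------------------------------------------------
# Synthetic coding-sequence complement


def synthetic_cds_complement(
    usage: Mapping[str, float],
    scale: float = 100.0,
    codons_per_gene: int = 300,
    seed: int = 0,
) -> list[str]:
    """Synthetic CDS set with exactly the given codon composition.

    Builds round(weight × scale) copies of each sense codon, shuffles
    their order (seeded; order does not affect site counting), and
    chunks them into pseudo-genes of ``codons_per_gene`` codons, each
    closed by a TAA terminal stop.  Because fractional site counts
    depend only on codon composition, the set reproduces the site
    counts implied by the usage table at any ``scale``.
    """
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    for codon in sorted(usage):
        pool.extend([codon] * int(round(usage[codon] * scale)))
    if not pool:
        raise ValueError("empty codon pool; increase scale")
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    genes = []
    for start in range(0, len(pool), codons_per_gene):
        genes.append("".join(pool[start : start + codons_per_gene]) + "TAA")
    return genes
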