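"""Stochastic clonal-evolution simulator with ground-truth phenotype labels.

Models a barcoded cell population split into one DMSO control arm and
several parallel drug-selected replicate arms, evolving in discrete
generations under a Wright-Fisher-with-selection scheme:

* each clone's cells first survive a binomial death draw (drug kill for
  sensitive cells, a small baseline turnover otherwise), then reproduce
  with a Poisson offspring number whose mean is the survivor count times
  a growth multiplier (a doubling base rate scaled by relative fitness);
* a small set of barcodes is resistant before treatment (*pre-existing*,
  identical across arms because all arms are split from one pool);
  sensitive cells convert to resistant at a low per-cell-per-generation
  rate under drug (*de novo*, replicate-private);
* optional *partially resistant* barcodes tolerate the starting dose but
  lose their advantage when the dose is escalated mid-course, which is
  what produces rise-then-fall trajectories after the switch from 1x to
  2x IC50;
* dead cells accumulate into the current medium-sampling interval
  (dead-cell shedding), and each week the dish is passaged down to a
  bottleneck size by a multivariate hypergeometric draw.

Sequencing is emulated by multinomial read sampling at a fixed depth,
optionally expanded into paired FASTQ with the amplicon read layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clonetrace.extract import (
    ARM_DMSO,
    ARM_INITIAL,
    ARM_MEDIUM_PREFIX,
    ARM_REPLICATE_PREFIX,
    BarcodeLibrary,
    CountMatrix,
    ReadStructure,
    merge_count_matrices,
    reverse_complement,
)

# population rows
_SENS, _RES, _PART = 0, 1, 2

TRUTH_PRE_EXISTING = "pre_existing_resistant"
TRUTH_DE_NOVO = "de_novo_resistant"
TRUTH_PARTIAL = "partial_resistant"
TRUTH_SENSITIVE = "sensitive"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one barcoded selection experiment.

    Defaults describe a six-month selection: 26 weeks at two generations
    per week, dose escalation after four months (week 17), three drug
    replicates plus a DMSO arm split from one shared pool, five
    equal-interval medium samplings, and a desk-scaled bottleneck of
    1e5 cells standing in for the experimental 2e6 per dish.
    """

    n_barcodes: int = 7000
    lognormal_sigma: float = 1.0  # initial clone-size spread
    frac_pre_existing_resistant: float = 0.01
    frac_partial_resistant: float = 0.002
    de_novo_rate: float = 1e-6  # per cell per generation at full scale, under drug only
    full_scale_population: int = 2_000_000  # dish size the desk-scaled bottleneck stands for
    fitness_sensitive: float = 0.35  # relative growth under drug
    fitness_resistant: float = 1.0
    fitness_no_drug: float = 1.0
    fitness_partial: float = 1.0  # at 1x IC50
    escalated_fitness_sensitive: float = 0.2  # at 2x IC50
    escalated_fitness_partial: float = 0.35
    death_fraction_per_generation: float = 0.5  # drug kill of sensitive cells
    baseline_death_fraction: float = 0.05  # turnover shed by all cells
    base_growth_factor: float = 2.0  # doublings per generation at fitness 1
    generations_per_week: int = 2
    total_weeks: int = 26
    dose_escalation_week: int = 17
    bottleneck_size: int = 100_000
    n_replicates: int = 3
    n_medium_samples: int = 5
    read_depth: int = 1_000_000
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.frac_pre_existing_resistant,
            self.frac_partial_resistant,
            self.de_novo_rate,
            self.death_fraction_per_generation,
            self.baseline_death_fraction,
            self.sequencing_error_rate,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.total_weeks <= 0 or self.read_depth < 0 or self.bottleneck_size <= 0:
            raise ValueError("weeks, depth and bottleneck must be positive")

    @property
    def effective_de_novo_rate(self) -> float:
        """Per-cell conversion probability at the simulated population scale.

        ``de_novo_rate`` is defined per cell of the full-scale dish; the
        desk-scaled population carries proportionally fewer cells, so the
        per-cell rate is scaled up to preserve the expected number of de
        novo events per arm.
        """
        return min(1.0, self.de_novo_rate * self.full_scale_population / self.bottleneck_size)

    @property
    def medium_sampling_weeks(self) -> list[int]:
        """Medium-change weeks at equal intervals over the course."""
        n = self.n_medium_samples
        return [round(self.total_weeks * k / n) for k in range(1, n + 1)]

    @property
    def replicate_names(self) -> list[str]:
        return [f"{ARM_REPLICATE_PREFIX}{chr(ord('A') + i)}" for i in range(self.n_replicates)]


@dataclass
class ArmResult:
    """Trajectory, endpoint and truth bookkeeping for one simulated arm."""

    arm: str
    history: np.ndarray  # (total_weeks + 1, n_barcodes) per-barcode cell totals
    final_pop: np.ndarray  # (3, n_barcodes) sensitive / resistant / partial cells
    shed: np.ndarray  # (n_medium_samples, n_barcodes) deaths per interval
    de_novo_week: dict[int, int]  # barcode index -> week of first conversion
    extinct: bool

    @property
    def final_sizes(self) -> np.ndarray:
        return self.final_pop.sum(axis=0)


def initial_population(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the shared founding pool as a (3, n_barcodes) cell-count array.

    Clone sizes follow a log-normal abundance distribution scaled to the
    bottleneck size; pre-existing resistant and partially resistant
    barcodes are chosen uniformly (disjointly) and their cells placed in
    the corresponding compartment.
    """
    B = cfg.n_barcodes
    weights = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=B)
    sizes = rng.multinomial(cfg.bottleneck_size, weights / weights.sum())
    n_pre = round(cfg.frac_pre_existing_resistant * B)
    n_part = round(cfg.frac_partial_resistant * B)
    special = rng.choice(B, size=n_pre + n_part, replace=False)
    pop = np.zeros((3, B), dtype=np.int64)
    pop[_SENS] = sizes
    for row, idx in ((_RES, special[:n_pre]), (_PART, special[n_pre:])):
        pop[row, idx] = pop[_SENS, idx]
        pop[_SENS, idx] = 0
    return pop


def _rates(cfg: SimulationConfig, arm: str, escalated: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-compartment death fractions and growth multipliers."""
    d0, db = cfg.death_fraction_per_generation, cfg.baseline_death_fraction
    g = cfg.base_growth_factor
    if arm == ARM_DMSO:
        death = np.array([db, db, db])
        mult = np.full(3, g * cfg.fitness_no_drug)
    elif not escalated:
        death = np.array([d0, db, db])
        mult = g * np.array([cfg.fitness_sensitive, cfg.fitness_resistant, cfg.fitness_partial])
    else:
        death = np.array([d0, db, d0])
        mult = g * np.array(
            [cfg.escalated_fitness_sensitive, cfg.fitness_resistant, cfg.escalated_fitness_partial]
        )
    return death, mult


def simulate_arm(
    cfg: SimulationConfig,
    arm: str,
    shared_initial_population: np.ndarray,
    rng: np.random.Generator,
) -> ArmResult:
    """Evolve one arm (``dmso`` or ``replicate-X``) from the shared pool.

    Within each generation: binomial survival (deaths shed into the
    current medium interval), Poisson reproduction scaled by fitness,
    then de novo sensitive-to-resistant conversion under drug.  At each
    week's end the population is passaged down to the bottleneck size by
    a multivariate hypergeometric draw.  Extinction is flagged, not raised.
    """
    B = cfg.n_barcodes
    pop = shared_initial_population.copy()
    history = np.zeros((cfg.total_weeks + 1, B), dtype=np.int64)
    history[0] = pop.sum(axis=0)
    shed = np.zeros((cfg.n_medium_samples, B), dtype=np.int64)
    boundaries = cfg.medium_sampling_weeks
    de_novo_week: dict[int, int] = {}
    under_drug = arm != ARM_DMSO

    for week in range(1, cfg.total_weeks + 1):
        interval = int(np.searchsorted(boundaries, week))
        interval = min(interval, cfg.n_medium_samples - 1)
        escalated = week >= cfg.dose_escalation_week
        death, mult = _rates(cfg, arm, escalated)
        for _ in range(cfg.generations_per_week):
            if pop.sum() == 0:
                break
            survivors = rng.binomial(pop, 1.0 - death[:, None])
            deaths = pop - survivors
            shed[interval] += deaths.sum(axis=0)
            pop = rng.poisson(survivors * mult[:, None])
            if under_drug and cfg.de_novo_rate > 0:
                conversions = rng.binomial(pop[_SENS], cfg.effective_de_novo_rate)
                converted = np.nonzero(conversions)[0]
                if converted.size:
                    pop[_SENS, converted] -= conversions[converted]
                    pop[_RES, converted] += conversions[converted]
                    for idx in converted:
                        de_novo_week.setdefault(int(idx), week)
        total = int(pop.sum())
        if total > cfg.bottleneck_size:
            flat = pop.reshape(-1)
            flat = rng.multivariate_hypergeometric(
                flat, cfg.bottleneck_size, method="marginals"
            )
            pop = flat.reshape(3, B)
        history[week] = pop.sum(axis=0)
    return ArmResult(
        arm=arm,
        history=history,
        final_pop=pop,
        shed=shed,
        de_novo_week=de_novo_week,
        extinct=bool(pop.sum() == 0),
    )


def emit_counts(
    sizes: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    barcode_ids: list[int] | np.ndarray,
    sample_id: str,
    arm: str,
) -> CountMatrix:
    """Multinomial read sampling of `depth` reads from clone frequencies."""
    sizes = np.asarray(sizes, dtype=float)
    total = sizes.sum()
    if depth == 0 or total == 0:
        counts = np.zeros(len(sizes), dtype=np.int64)
    else:
        counts = rng.multinomial(depth, sizes / total)
    df = pd.DataFrame({sample_id: counts}, index=pd.Index(barcode_ids, name="barcode_id"))
    return CountMatrix(
        counts=df, arms={sample_id: arm}, total_reads={sample_id: int(counts.sum())}
    )


def emit_medium_series(
    shed: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    barcode_ids: list[int] | np.ndarray,
    replicate: str,
) -> list[CountMatrix]:
    """One multinomial medium sample per shedding interval."""
    out = []
    for k in range(shed.shape[0]):
        out.append(
            emit_counts(
                shed[k],
                depth,
                rng,
                barcode_ids,
                sample_id=f"{replicate}-medium-{k + 1}",
                arm=f"{ARM_MEDIUM_PREFIX}{k + 1}",
            )
        )
    return out


def random_library(
    n: int, rng: np.random.Generator, length: int = 48, start_id: int = 1
) -> BarcodeLibrary:
    """Random whitelist of `n` distinct ACGT barcodes of the given length."""
    bases = np.array(list("ACGT"))
    seqs: set[str] = set()
    ordered: list[str] = []
    while len(ordered) < n:
        draw = rng.integers(0, 4, size=(n - len(ordered), length))
        for row in draw:
            seq = "".join(bases[row])
            if seq not in seqs:
                seqs.add(seq)
                ordered.append(seq)
    return BarcodeLibrary(ids=list(range(start_id, start_id + n)), sequences=ordered)


def _constant_flanks(rs: ReadStructure, read_len: int = 150) -> tuple[str, str, str, str]:
    # fixed arbitrary constant context shared by every simulated amplicon
    flank_rng = np.random.default_rng(20230711)
    bases = np.array(list("ACGT"))

    def seq(n: int) -> str:
        return "".join(bases[flank_rng.integers(0, 4, size=n)]) if n > 0 else ""

    fwd_flank = seq(rs.fwd_headcrop)
    fwd_tail = seq(read_len - rs.fwd_headcrop - rs.fwd_croplen)
    rev_flank = seq(rs.rev_headcrop)
    rev_tail = seq(read_len - rs.rev_headcrop - rs.rev_croplen)
    return fwd_flank, fwd_tail, rev_flank, rev_tail


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        alternatives = bases[bases != arr[i]]
        arr[i] = rng.choice(alternatives)
    return arr.tobytes().decode()


def emit_fastq(
    cm: CountMatrix,
    sample_id: str,
    lib: BarcodeLibrary,
    rs: ReadStructure,
    error_rate: float,
    rng: np.random.Generator,
    r1_path: str | Path,
    r2_path: str | Path,
    read_len: int = 150,
    qual_char: str = "F",  # Phred 37
) -> int:
    """Expand one sample's counts into a paired FASTQ amplicon run.

    Each count becomes one read pair laid out per ``rs``: constant flank,
    the barcode 48-mer (reverse-complemented on mate 2), and constant
    tail padding to ``read_len``.  Substitution errors are applied at
    ``error_rate`` per base.  Returns the number of pairs written.
    """
    id_to_seq = dict(zip(lib.ids, lib.sequences))
    fwd_flank, fwd_tail, rev_flank, rev_tail = _constant_flanks(rs, read_len)
    qual = qual_char * read_len
    counts = cm.counts[sample_id]
    present = counts[counts > 0]
    missing = set(present.index) - set(id_to_seq)
    if missing:
        raise ValueError(f"barcode IDs absent from library: {sorted(missing)[:5]}")
    # expand and shuffle so read order carries no signal
    expanded = np.repeat(present.index.to_numpy(), present.to_numpy())
    rng.shuffle(expanded)
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for bc_id in expanded:
            bc = id_to_seq[int(bc_id)]
            mate1 = _add_errors(fwd_flank + bc + fwd_tail, error_rate, rng)
            mate2 = _add_errors(rev_flank + reverse_complement(bc) + rev_tail, error_rate, rng)
            n += 1
            f1.write(f"@sim_{sample_id}_{n}/1\n{mate1}\n+\n{qual}\n")
            f2.write(f"@sim_{sample_id}_{n}/2\n{mate2}\n+\n{qual}\n")
    return n


@dataclass
class ExperimentResult:
    """Everything one simulated experiment produced, plus its truth channel."""

    config: SimulationConfig
    endpoint: CountMatrix  # initial + dmso + replicate endpoint samples
    medium: dict[str, list[CountMatrix]]  # replicate -> per-interval samples
    arms: dict[str, ArmResult]
    truth: pd.DataFrame  # barcode_id x (truth_class, de_novo reps, endpoint freqs)
    initial_pop: np.ndarray = field(repr=False, default=None)

    def truth_label(self, barcode_id: int, replicate: str) -> str:
        row = self.truth.loc[barcode_id]
        if row["truth_class"] == TRUTH_PRE_EXISTING:
            return TRUTH_PRE_EXISTING
        if replicate in row["de_novo_replicates"].split(","):
            return TRUTH_DE_NOVO
        if row["truth_class"] == TRUTH_PARTIAL:
            return TRUTH_PARTIAL
        return TRUTH_SENSITIVE


def run_experiment(cfg: SimulationConfig) -> ExperimentResult:
    """Simulate all arms from one shared pool and emit endpoint + medium counts."""
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(2 + cfg.n_replicates + 1)
    init_rng = np.random.Generator(np.random.PCG64(streams[0]))
    seq_rng = np.random.Generator(np.random.PCG64(streams[1]))

    pop0 = initial_population(cfg, init_rng)
    barcode_ids = np.arange(1, cfg.n_barcodes + 1)

    arms: dict[str, ArmResult] = {}
    arm_names = [ARM_DMSO] + cfg.replicate_names
    for i, arm in enumerate(arm_names):
        arm_rng = np.random.Generator(np.random.PCG64(streams[2 + i]))
        arms[arm] = simulate_arm(cfg, arm, pop0, arm_rng)

    parts = [
        emit_counts(pop0.sum(axis=0), cfg.read_depth, seq_rng, barcode_ids, ARM_INITIAL, ARM_INITIAL),
        emit_counts(
            arms[ARM_DMSO].final_sizes, cfg.read_depth, seq_rng, barcode_ids, ARM_DMSO, ARM_DMSO
        ),
    ]
    for rep in cfg.replicate_names:
        parts.append(
            emit_counts(arms[rep].final_sizes, cfg.read_depth, seq_rng, barcode_ids, rep, rep)
        )
    endpoint = merge_count_matrices(parts)

    medium = {
        rep: emit_medium_series(arms[rep].shed, cfg.read_depth, seq_rng, barcode_ids, rep)
        for rep in cfg.replicate_names
    }

    pre_mask = pop0[_RES] > 0
    part_mask = pop0[_PART] > 0
    truth_class = np.where(
        pre_mask, TRUTH_PRE_EXISTING, np.where(part_mask, TRUTH_PARTIAL, TRUTH_SENSITIVE)
    )
    de_novo_reps = ["" for _ in range(cfg.n_barcodes)]
    for rep in cfg.replicate_names:
        for idx in arms[rep].de_novo_week:
            de_novo_reps[idx] = f"{de_novo_reps[idx]},{rep}".lstrip(",")
    truth = pd.DataFrame(
        {
            "truth_class": truth_class,
            "de_novo_replicates": de_novo_reps,
        },
        index=pd.Index(barcode_ids, name="barcode_id"),
    )
    for rep in cfg.replicate_names:
        sizes = arms[rep].final_sizes
        total = sizes.sum()
        truth[f"endpoint_freq_{rep}"] = sizes / total if total else 0.0
    return ExperimentResult(
        config=cfg, endpoint=endpoint, medium=medium, arms=arms, truth=truth, initial_pop=pop0
    )
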