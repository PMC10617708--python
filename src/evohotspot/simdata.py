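"""Seeded synthetic data emulating an experimental-evolution resistance study.

The generator stands in for the raw data of a cohort study in which
hundreds of haploid drug-resistant mutants, evolved from two genetic
backgrounds, are whole-genome sequenced and phenotyped.  It produces
every input the analysis pipeline consumes:

* a toy reference genome with a configurable GC profile along each
  chromosome, and intronless gene models including one designated
  **hotspot gene** (the mutational target of resistance);
* a truth set of mutants: most carry exactly one planted causal
  loss-of-function mutation, concentrated in the hotspot gene, plus
  Poisson background mutations and background-wide parental variants;
  mutants are grouped into precultures, and one preculture can be
  flagged as carrying a shared (pre-existing) causal mutation;
* caller-specific variant tables: each caller profile has its own
  sensitivity, false-positive rate, and annotation-value distributions,
  with a configurable fraction of true calls drawn from the failing side
  of the hard-filter thresholds;
* windowed read-coverage tracks with GC bias, chromosome-end inflation
  and planted copy-number changes;
* logistic growth curves with genotype-by-medium effects, Hill
  dose-response observations, and bimodal flow-cytometry event tables.

Determinism: a single master seed; each component draws from its own
child generator keyed by a fixed component offset, so the same
(seed, config) always reproduces byte-identical outputs and components
can be regenerated independently.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .variants import GeneModel, SampleCall, VariantRecord, VariantTable

__all__ = [
    "SimConfig",
    "CallerProfile",
    "BiasConfig",
    "GrowthParams",
    "FlowPopulation",
    "Genome",
    "PlantedVariant",
    "MutantTruth",
    "TruthSet",
    "generate_genome",
    "simulate_cohort",
    "emit_caller_calls",
    "simulate_coverage_track",
    "simulate_growth",
    "simulate_dose_response",
    "simulate_flow_sample",
    "DEFAULT_CALLER_PROFILES",
    "DEFAULT_MEDIA_PANEL",
]

_BASES = np.array(list("ACGT"))

# fixed per-component offsets for child generators (determinism contract)
_SEED_OFFSETS = {
    "genome": 11,
    "cohort": 23,
    "caller": 37,
    "coverage": 53,
    "growth": 71,
    "dose": 89,
    "flow": 101,
}


def _child_rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([_SEED_OFFSETS[component], int(seed), int(extra)])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnnotationSpec:
    """Truncated-normal sampler for one site annotation, pass and fail sides."""

    pass_mean: float
    pass_sd: float
    pass_lo: float
    pass_hi: float
    fail_mean: float
    fail_sd: float
    fail_lo: float
    fail_hi: float

    def draw(self, rng: np.random.Generator, failing: bool) -> float:
        return float(self.draw_many(rng, 1, failing)[0])

    def draw_many(
        self, rng: np.random.Generator, n: int, failing: bool
    ) -> np.ndarray:
        mean, sd, lo, hi = (
            (self.fail_mean, self.fail_sd, self.fail_lo, self.fail_hi)
            if failing
            else (self.pass_mean, self.pass_sd, self.pass_lo, self.pass_hi)
        )
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


# pass side clears every hard-filter threshold; fail side violates at least
# the named rule's threshold
_DEFAULT_ANNOTATION_SPECS = {
    "QUAL": AnnotationSpec(900.0, 400.0, 31.0, 5000.0, 15.0, 8.0, 0.0, 29.9),
    "QD": AnnotationSpec(22.0, 6.0, 2.1, 40.0, 1.0, 0.5, 0.0, 1.9),
    "MQ": AnnotationSpec(58.0, 1.5, 40.1, 60.0, 25.0, 8.0, 0.0, 39.9),
    "FS": AnnotationSpec(3.0, 2.5, 0.0, 59.0, 120.0, 40.0, 61.0, 400.0),
    "SOR": AnnotationSpec(1.0, 0.6, 0.0, 3.9, 6.0, 1.5, 4.1, 12.0),
    "MQRankSum": AnnotationSpec(0.0, 1.5, -12.0, 12.0, -20.0, 4.0, -40.0, -13.0),
    "ReadPosRankSum": AnnotationSpec(0.0, 1.5, -7.5, 7.5, -13.0, 2.5, -25.0, -8.5),
}


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one variant caller.

    ``sensitivity`` is the per-variant per-genome detection probability;
    ``fp_rate`` the Poisson mean of false-positive calls per genome.
    ``true_fail_fraction`` of true calls draw one annotation from the
    failing side of its hard-filter threshold (so filters have work to
    do without destroying signal); false positives are low-quality calls
    and fail at ``fp_fail_fraction``.
    """

    name: str
    sensitivity: float = 0.95
    fp_rate: float = 4.0
    true_fail_fraction: float = 0.05
    fp_fail_fraction: float = 0.6
    dp_mean: float = 60.0
    contamination_rate: float = 0.04
    low_dp_rate: float = 0.02
    annotation_specs: dict = field(
        default_factory=lambda: dict(_DEFAULT_ANNOTATION_SPECS)
    )

    def __post_init__(self) -> None:
        for p in (self.sensitivity, self.true_fail_fraction, self.fp_fail_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probabilities must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError(f"{self.name}: fp_rate must be >= 0")


# the permissive caller detects more (incl. indels) but with noisier calls;
# the stringent one misses indels and rare alleles but rarely false-calls
DEFAULT_CALLER_PROFILES = {
    "tolerant": CallerProfile(name="tolerant", sensitivity=0.97, fp_rate=6.0,
                              true_fail_fraction=0.05, fp_fail_fraction=0.55),
    "stringent": CallerProfile(name="stringent", sensitivity=0.85, fp_rate=1.0,
                               true_fail_fraction=0.05, fp_fail_fraction=0.35),
}


@dataclass(frozen=True)
class BiasConfig:
    """Coverage-track biases: base depth, GC slope, end inflation."""

    base_depth: float = 60.0  # mean per-position depth, as in ~60X WGS
    gc_slope: float = 0.0  # multiplier 1 + gc_slope * (gc - gc_ref)
    gc_ref: float = 0.40
    end_ramp_factor: float = 1.0  # multiplier at the terminal base
    end_ramp_scale_bp: float = 20000.0  # decay length of the inflation
    end_ramp_shape: str = "exp"  # "exp" (sharp spike) | "linear" (broad ramp)

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.end_ramp_shape not in ("exp", "linear"):
            raise ValueError(f"unknown end_ramp_shape {self.end_ramp_shape!r}")

    def gc_multiplier(self, gc: float) -> float:
        return max(0.05, 1.0 + self.gc_slope * (gc - self.gc_ref))

    def end_multiplier(self, dist_to_end: float) -> float:
        if self.end_ramp_factor == 1.0:
            return 1.0
        if self.end_ramp_shape == "linear":
            frac = max(0.0, 1.0 - dist_to_end / self.end_ramp_scale_bp)
        else:
            frac = math.exp(-dist_to_end / self.end_ramp_scale_bp)
        return 1.0 + (self.end_ramp_factor - 1.0) * frac


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters for one (genotype class, medium) cell."""

    k: float  # carrying capacity (AU)
    r: float  # max specific growth rate (per hour)
    lag_h: float = 2.0
    x0: float = 0.01

    def __post_init__(self) -> None:
        if self.k <= 0 or self.x0 <= 0:
            raise ValueError("carrying capacity and inoculum must be positive")


# genotype-by-medium growth: resistance helps only under drug, at a small
# drug-free cost; sensitive strains are strongly inhibited by the drug
DEFAULT_MEDIA_PANEL = {
    ("wt", "minimal"): GrowthParams(k=1.0, r=0.35),
    ("wt", "minimal+drug"): GrowthParams(k=0.35, r=0.06),
    ("resistant", "minimal"): GrowthParams(k=1.0, r=0.33),
    ("resistant", "minimal+drug"): GrowthParams(k=1.0, r=0.32),
    ("sensitive", "minimal"): GrowthParams(k=1.0, r=0.35),
    ("sensitive", "minimal+drug"): GrowthParams(k=0.35, r=0.06),
}


@dataclass(frozen=True)
class FlowPopulation:
    """Log-normal event cloud in FSC/SSC and two fluorescence channels."""

    fsc_log_mean: float = math.log(5000.0)
    fsc_log_sd: float = 0.35
    ssc_log_mean: float = math.log(1500.0)
    ssc_log_sd: float = 0.4
    green_log_mean: float = math.log(50.0)
    green_log_sd: float = 0.5
    orange_log_mean: float = math.log(50.0)
    orange_log_sd: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Master configuration of the synthetic study.

    Defaults mirror the emulated study at desk scale: two genetic
    backgrounds, ~25 precultures each, one hotspot gene collecting 90%
    of causal loss-of-function mutations, haploid genotypes, ~60X
    coverage.  ``hotspot_fraction`` plus the alternative-gene
    probabilities must not exceed 1; the remainder is the fraction of
    mutants with no identified causal gene.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 200_000
    gc_base: float = 0.40
    gc_amplitude: float = 0.08  # GC varies sinusoidally in [gc_base +/- amp]
    gc_period_bp: int = 50_000
    genes_per_chromosome: int = 10
    gene_cds_bp: int = 651  # divisible by 3
    gene_spacing_bp: int = 20_000
    promoter_window_bp: int = 500
    hotspot_gene_id: str = "FUR1"
    n_mutants_per_background: int = 138
    n_precultures: int = 25  # per background
    hotspot_fraction: float = 0.90
    alt_gene_probs: dict = field(default_factory=dict)  # gene_id -> probability
    effect_class_probs: dict = field(
        default_factory=lambda: {
            "missense": 0.55,
            "stop_gained": 0.25,
            "frameshift": 0.15,
            "start_lost": 0.05,
        }
    )
    background_noise_mean: float = 3.0  # Poisson background variants per genome
    parental_variant_count: int = 20  # per background, shared by all its mutants
    petite_fraction: tuple = (0.28, 0.36)  # rho- fraction per background
    shared_preculture_size: int = 0  # members of one shared-mutation preculture
    cnv_plants: tuple = ()  # (chrom, start, end, copy_ratio)

    def __post_init__(self) -> None:
        if self.chromosome_length_bp < 20_000:
            raise ValueError("chromosome_length_bp must be >= 20,000")
        total_p = self.hotspot_fraction + sum(self.alt_gene_probs.values())
        if not 0.0 <= total_p <= 1.0 + 1e-12:
            raise ValueError(
                "hotspot_fraction plus alternative-gene probabilities must be <= 1"
            )
        if abs(sum(self.effect_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("effect_class_probs must sum to 1")
        if self.gene_cds_bp % 3:
            raise ValueError("gene_cds_bp must be divisible by 3")
        for chrom, start, end, ratio in self.cnv_plants:
            if not (0 <= start < end <= self.chromosome_length_bp):
                raise ValueError(
                    f"planted CNV {chrom}:{start}-{end} outside chromosome bounds"
                )
            if ratio <= 0:
                raise ValueError("CNV copy_ratio must be positive")

    @property
    def backgrounds(self) -> tuple[str, str]:
        return ("A", "B")


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class Genome:
    sequences: dict  # chrom -> str
    genes: tuple  # GeneModel, ascending by (chrom, start)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _gc_profile(config: SimConfig, positions: np.ndarray) -> np.ndarray:
    gc = config.gc_base + config.gc_amplitude * np.sin(
        2 * np.pi * positions / config.gc_period_bp
    )
    return np.clip(gc, 0.25, 0.55)


def generate_genome(config: SimConfig) -> Genome:
    """Deterministically build the reference sequences and gene models.

    Per-position GC follows the configured sinusoidal profile (clipped
    to [0.25, 0.55]).  ``genes_per_chromosome`` intronless genes of
    ``gene_cds_bp`` are placed at regular spacing with alternating
    strands; each CDS starts with ATG and ends with a stop codon.  The
    hotspot gene is the first gene of the first chromosome.
    """
    rng = _child_rng(config.seed, "genome")
    needed = config.gene_spacing_bp * config.genes_per_chromosome
    if needed > config.chromosome_length_bp:
        raise ValueError(
            f"{config.genes_per_chromosome} genes at spacing "
            f"{config.gene_spacing_bp} bp do not fit in "
            f"{config.chromosome_length_bp} bp chromosomes"
        )
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = np.arange(config.chromosome_length_bp)
        gc = _gc_profile(config, pos)
        p_gc = gc / 2.0
        probs = np.column_stack(
            [(1 - gc) / 2, p_gc, p_gc, (1 - gc) / 2]
        )  # A, C, G, T
        u = rng.random(config.chromosome_length_bp)
        cum = np.cumsum(probs, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        seq = np.array(_BASES)[idx]
        for gi in range(config.genes_per_chromosome):
            start = config.promoter_window_bp + gi * config.gene_spacing_bp
            end = start + config.gene_cds_bp
            strand = "+" if (gi % 2 == 0) else "-"
            if ci == 0 and gi == 0:
                gene_id = config.hotspot_gene_id
            else:
                gene_id = f"g{ci + 1:02d}{gi:02d}"
            cds = _random_cds(rng, config.gene_cds_bp)
            oriented = cds if strand == "+" else str(Seq(cds).reverse_complement())
            seq[start:end] = list(oriented)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    cds=((start, end),),
                    promoter_window_bp=config.promoter_window_bp,
                )
            )
        sequences[chrom] = "".join(seq)
    return Genome(sequences=sequences, genes=tuple(genes))


_STOPS = ("TAA", "TAG", "TGA")


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random internal non-stop codons + one stop codon (5'->3')."""
    n_internal = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_internal + 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# cohort truth


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos0: int  # 0-based
    ref: str
    alt: str
    gene_id: str | None = None
    effect_class: str | None = None

    @property
    def pos1(self) -> int:
        return self.pos0 + 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos1, self.ref, self.alt)


@dataclass(frozen=True)
class MutantTruth:
    mutant_id: str
    background: str
    preculture: str
    rho_status: str  # "rho+" | "rho-"
    causal: PlantedVariant | None
    background_variants: tuple


@dataclass(frozen=True)
class TruthSet:
    mutants: tuple  # MutantTruth
    parental_variants: dict  # background -> tuple[PlantedVariant]
    cnv_plants: tuple
    config: SimConfig

    def by_background(self, background: str) -> tuple:
        return tuple(m for m in self.mutants if m.background == background)

    def causal_assignments(self) -> dict:
        """mutant_id -> causal variant key (or None), for sharing analyses."""
        return {
            m.mutant_id: (m.causal.key if m.causal else None) for m in self.mutants
        }


def _plant_effect_variant(
    rng: np.random.Generator, genome: Genome, gene: GeneModel, effect_class: str
) -> PlantedVariant:
    """Place one variant of the requested class inside the gene's CDS."""
    seq = genome.sequences[gene.chrom]
    start, end = gene.span

    def base_at(p):
        return seq[p]

    if effect_class == "start_lost":
        # mutate one base of the start codon so it no longer encodes M
        codon_pos = range(3) if gene.strand == "+" else range(3)
        offsets = [
            (start + i) if gene.strand == "+" else (end - 1 - i) for i in codon_pos
        ]
        for _ in range(50):
            p = int(rng.choice(offsets))
            ref = base_at(p)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            if _snp_effect(genome, gene, p, ref, alt) == "start_lost":
                return PlantedVariant(gene.chrom, p, ref, alt, gene.gene_id, effect_class)
        effect_class = "missense"  # rare fallback: degenerate start context
    if effect_class == "frameshift":
        p = int(rng.integers(start + 3, end - 3))
        if rng.random() < 0.5:
            ref = seq[p - 1 : p + 1]
            return PlantedVariant(gene.chrom, p - 1, ref, ref[0], gene.gene_id, effect_class)
        ref = base_at(p)
        ins = str(rng.choice(list("ACGT")))
        return PlantedVariant(gene.chrom, p, ref, ref + ins, gene.gene_id, effect_class)
    # SNP classes: rejection-sample positions until the class matches
    for _ in range(2000):
        p = int(rng.integers(start, end))
        ref = base_at(p)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if _snp_effect(genome, gene, p, ref, alt) == effect_class:
            return PlantedVariant(gene.chrom, p, ref, alt, gene.gene_id, effect_class)
    raise RuntimeError(
        f"could not plant a {effect_class} variant in {gene.gene_id}"
    )


def _snp_effect(genome: Genome, gene: GeneModel, pos0: int, ref: str, alt: str) -> str:
    offset = gene.cds_offset(pos0)
    ci, within = divmod(offset, 3)
    seq = "".join(genome.sequences[gene.chrom][s:e] for s, e in gene.cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    codon = seq[3 * ci : 3 * ci + 3]
    new = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new).translate())
    if ci == 0 and aa_ref == "M" and aa_alt != "M":
        return "start_lost"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    return "synonymous" if aa_ref == aa_alt else "missense"


def _random_snv(rng: np.random.Generator, genome: Genome) -> PlantedVariant:
    chrom = str(rng.choice(sorted(genome.sequences)))
    p = int(rng.integers(len(genome.sequences[chrom])))
    ref = genome.sequences[chrom][p]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return PlantedVariant(chrom, p, ref, alt)


def simulate_cohort(genome: Genome, config: SimConfig) -> TruthSet:
    """Plant causal, background and parental variants for every mutant.

    Each mutant draws a causal gene (the hotspot with probability
    ``hotspot_fraction``, alternatives per ``alt_gene_probs``, else no
    identified causal gene) and an effect class, then a concrete variant
    is planted in that gene's CDS.  Background noise variants are
    uniform over the genome (Poisson count per genome); parental
    variants are shared by every mutant of a background.  Precultures
    are assigned round-robin; if ``shared_preculture_size`` > 0 the
    first preculture of background A instead receives that many mutants
    all carrying one identical causal variant (a mutation that was
    already segregating in the preculture).
    """
    rng = _child_rng(config.seed, "cohort")
    gene_ids = [config.hotspot_gene_id, *config.alt_gene_probs]
    probs = [config.hotspot_fraction, *config.alt_gene_probs.values()]
    p_none = max(0.0, 1.0 - sum(probs))
    gene_ids.append(None)
    probs.append(p_none)
    effect_names = list(config.effect_class_probs)
    effect_p = list(config.effect_class_probs.values())

    parental = {}
    for background in config.backgrounds:
        parental[background] = tuple(
            _random_snv(rng, genome) for _ in range(config.parental_variant_count)
        )

    mutants: list[MutantTruth] = []
    shared_variant: PlantedVariant | None = None
    if config.shared_preculture_size > 0:
        gene = genome.gene(config.hotspot_gene_id)
        shared_variant = _plant_effect_variant(rng, genome, gene, "missense")

    # a causal variant may recur within a preculture (pre-existing mutation)
    # but never across precultures: those are independent origins
    causal_owner: dict[tuple, str] = {}
    if shared_variant is not None:
        causal_owner[shared_variant.key] = "A_p00"

    for bi, background in enumerate(config.backgrounds):
        petite_p = config.petite_fraction[bi % len(config.petite_fraction)]
        n_shared = config.shared_preculture_size if background == "A" else 0
        n_rr = config.n_precultures - (1 if n_shared else 0)
        for mi in range(config.n_mutants_per_background):
            mutant_id = f"{background}_m{mi:03d}"
            if mi < n_shared:
                preculture = f"{background}_p00"
                causal = shared_variant
            else:
                first = 1 if n_shared else 0
                preculture = f"{background}_p{first + (mi % n_rr):02d}"
                gene_choice = gene_ids[
                    int(rng.choice(len(gene_ids), p=np.array(probs) / sum(probs)))
                ]
                if gene_choice is None:
                    causal = None
                else:
                    effect = str(
                        rng.choice(effect_names, p=np.array(effect_p))
                    )
                    # small effect classes (e.g. start-lost: 9 possible
                    # substitutions) can saturate across precultures; fall
                    # back to missense, whose variant space is vast
                    causal = None
                    for attempt_class in (effect, effect, "missense"):
                        for _ in range(30):
                            cand = _plant_effect_variant(
                                rng, genome, genome.gene(gene_choice), attempt_class
                            )
                            owner = causal_owner.setdefault(cand.key, preculture)
                            if owner == preculture:
                                causal = cand
                                break
                        if causal is not None:
                            break
                    if causal is None:  # pragma: no cover - saturated gene
                        raise RuntimeError(
                            f"cannot plant an unshared variant in {gene_choice}"
                        )
            n_bg = int(rng.poisson(config.background_noise_mean))
            bg_variants = tuple(_random_snv(rng, genome) for _ in range(n_bg))
            rho = "rho-" if rng.random() < petite_p else "rho+"
            mutants.append(
                MutantTruth(
                    mutant_id=mutant_id,
                    background=background,
                    preculture=preculture,
                    rho_status=rho,
                    causal=causal,
                    background_variants=bg_variants,
                )
            )
    return TruthSet(
        mutants=tuple(mutants),
        parental_variants=parental,
        cnv_plants=tuple(config.cnv_plants),
        config=config,
    )


# ---------------------------------------------------------------------------
# caller emission


def _parental_sample(background: str) -> str:
    return f"{background}_parent"


def emit_caller_calls(
    truth: TruthSet,
    profile: CallerProfile,
    background: str,
    seed_extra: int = 0,
) -> VariantTable:
    """Emit one caller's variant table for one background cohort.

    True variants (causal + background noise + parental) are detected
    per genome with probability ``profile.sensitivity``; Poisson false
    positives are added per genome.  Every emitted record carries
    QUAL/QD/MQ/FS/SOR/MQRankSum/ReadPosRankSum drawn from the profile's
    truncated-normal distributions (a configurable fraction from the
    failing side of one threshold) and per-sample GT/DP/AD; carriers of
    other sites get clean homozygous-reference calls, with occasional
    low-depth or contaminated calls to exercise the sample mask.
    """
    # stable (process-independent) key for this caller x cohort stream
    stream = zlib.crc32(f"{profile.name}/{background}/{seed_extra}".encode())
    rng = _child_rng(truth.config.seed, "caller", extra=stream)
    cohort = truth.by_background(background)
    samples = [m.mutant_id for m in cohort] + [_parental_sample(background)]
    carriers: dict[tuple, dict] = {}

    def add(variant: PlantedVariant, sample: str) -> None:
        entry = carriers.setdefault(
            variant.key, {"variant": variant, "samples": set(), "fp": False}
        )
        entry["samples"].add(sample)

    for m in cohort:
        for v in ([m.causal] if m.causal else []) + list(m.background_variants):
            if rng.random() < profile.sensitivity:
                add(v, m.mutant_id)
    for v in truth.parental_variants[background]:
        for sample in samples:  # parental variants are fixed in the background
            if rng.random() < profile.sensitivity:
                add(v, sample)
    # false positives: singleton low-confidence calls
    genome_ref = {
        chrom: seq for chrom, seq in _genome_from_truth(truth).items()
    }
    for m in cohort:
        for _ in range(int(rng.poisson(profile.fp_rate))):
            chrom = str(rng.choice(sorted(genome_ref)))
            p = int(rng.integers(len(genome_ref[chrom])))
            ref = genome_ref[chrom][p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = PlantedVariant(chrom, p, ref, alt)
            entry = carriers.setdefault(
                v.key, {"variant": v, "samples": set(), "fp": True}
            )
            entry["samples"].add(m.mutant_id)

    ordered = sorted(carriers, key=lambda k: (k[0], k[1], k[3]))
    n_rec = len(ordered)
    n_smp = len(samples)
    rules = ("QUAL", "QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

    # annotation values drawn in bulk: one failing rule per flagged record
    fail_p = np.array(
        [
            profile.fp_fail_fraction if carriers[k]["fp"] else profile.true_fail_fraction
            for k in ordered
        ]
    )
    flagged = rng.random(n_rec) < fail_p
    failing_idx = np.where(flagged, rng.integers(0, len(rules), size=n_rec), -1)
    values: dict[str, np.ndarray] = {}
    for ri, rule in enumerate(rules):
        spec = profile.annotation_specs[rule]
        values[rule] = np.where(
            failing_idx == ri,
            spec.draw_many(rng, n_rec, failing=True),
            spec.draw_many(rng, n_rec, failing=False),
        )

    # per-sample depths and contamination, vectorized per record
    records = []
    for i, key in enumerate(ordered):
        entry = carriers[key]
        variant: PlantedVariant = entry["variant"]
        low = rng.random(n_smp) < profile.low_dp_rate
        dp = np.where(low, rng.poisson(2.0, n_smp), rng.poisson(profile.dp_mean, n_smp))
        contam = (dp > 0) & (rng.random(n_smp) < profile.contamination_rate)
        minor = np.where(
            contam, np.round(dp * rng.uniform(0.05, 0.5, n_smp)).astype(int), 0
        )
        major = dp - minor
        calls = {}
        for si, sample in enumerate(samples):
            carrier = sample in entry["samples"]
            ad = (
                (int(minor[si]), int(major[si]))
                if carrier
                else (int(major[si]), int(minor[si]))
            )
            calls[sample] = SampleCall(sample, 1 if carrier else 0, int(dp[si]), ad)
        n_alt = len(entry["samples"])
        annotations = {rule: float(values[rule][i]) for rule in rules if rule != "QUAL"}
        annotations["DP"] = float(dp.sum())
        annotations["AC"] = float(n_alt)
        annotations["AF"] = n_alt / n_smp
        records.append(
            VariantRecord(
                chrom=variant.chrom,
                pos=variant.pos1,
                ref=variant.ref,
                alt=variant.alt,
                qual=float(values["QUAL"][i]),
                annotations=annotations,
                calls=calls,
            )
        )
    return VariantTable(records=records, samples=samples, caller=profile.name)


def _genome_from_truth(truth: TruthSet) -> dict:
    """Reference sequences regenerated from the truth set's config."""
    return generate_genome(truth.config).sequences


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage_track(
    genome: Genome,
    config: SimConfig,
    bias: BiasConfig | None = None,
    window: int = 5000,
    seed_extra: int = 0,
) -> pd.DataFrame:
    """Windowed read counts with GC bias, end inflation and planted CNVs.

    Each window's count is Poisson with mean
    ``base_depth * gc_multiplier(gc) * end_multiplier(distance) *
    copy_ratio`` — the generative inverse of the normalization the CNV
    module performs.  Returns a DataFrame with columns
    ``chrom, start, end, raw_mean_count, gc, normalized`` (normalized is
    NaN until the pipeline fills it).
    """
    bias = bias or BiasConfig()
    rng = _child_rng(config.seed, "coverage", extra=seed_extra)
    rows = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        length = len(seq)
        for start in range(0, length, window):
            end = min(start + window, length)
            sub = seq[start:end]
            gc = (sub.count("G") + sub.count("C")) / len(sub)
            center = (start + end) / 2.0
            dist = min(center, length - center)
            ratio = 1.0
            for c_chrom, c_start, c_end, c_ratio in config.cnv_plants:
                if c_chrom == chrom and c_start < end and start < c_end:
                    ratio = c_ratio
                    break
            lam = (
                bias.base_depth
                * bias.gc_multiplier(gc)
                * bias.end_multiplier(dist)
                * ratio
            )
            # Poisson over per-position reads, reported as mean depth
            count = rng.poisson(lam * (end - start)) / (end - start)
            rows.append((chrom, start, end, float(count), gc, np.nan))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "raw_mean_count", "gc", "normalized"]
    )


# ---------------------------------------------------------------------------
# growth, dose-response, flow


def _genotype_class(mutant: MutantTruth, hotspot_gene_id: str) -> str:
    if mutant.causal is None:
        return "sensitive"
    return "resistant"


def simulate_growth(
    truth: TruthSet,
    media_panel: dict | None = None,
    media=("minimal", "minimal+drug"),
    n_replicates: int = 4,
    t_max_h: float = 22.0,
    dt_h: float = 2.0,
    noise_sd: float = 0.05,
    strains=None,
    seed_extra: int = 0,
) -> pd.DataFrame:
    """Logistic growth time series per strain, medium and replicate.

    Curves follow x(t) = K / (1 + ((K - x0)/x0) e^(-r (t - lag))) (flat
    at x0 before the lag) with multiplicative log-normal noise, sampled
    every ``dt_h`` hours up to ``t_max_h``.  Wild-type replicates for
    each background are always included, enabling WT-normalized fitness
    downstream.  Returns a tidy DataFrame
    (strain, medium, replicate, time_h, value).
    """
    panel = media_panel or DEFAULT_MEDIA_PANEL
    rng = _child_rng(truth.config.seed, "growth", extra=seed_extra)
    times = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    chosen = truth.mutants if strains is None else [
        m for m in truth.mutants if m.mutant_id in set(strains)
    ]
    rows = []

    def curve(params: GrowthParams) -> np.ndarray:
        t_eff = np.maximum(times - params.lag_h, 0.0)
        a = (params.k - params.x0) / params.x0
        return params.k / (1.0 + a * np.exp(-params.r * t_eff))

    roster = [("WT_" + bg, "wt") for bg in truth.config.backgrounds]
    roster += [
        (m.mutant_id, _genotype_class(m, truth.config.hotspot_gene_id))
        for m in chosen
    ]
    for strain, cls in roster:
        for medium in media:
            params = panel[(cls, medium)]
            base = curve(params)
            for rep in range(n_replicates):
                noise = (
                    np.exp(rng.normal(0.0, noise_sd, size=len(times)))
                    if noise_sd > 0
                    else 1.0
                )
                values = base * noise
                rows.extend(
                    (strain, medium, f"r{rep + 1}", float(t), float(v))
                    for t, v in zip(times, values)
                )
    return pd.DataFrame(
        rows, columns=["strain", "medium", "replicate", "time_h", "value"]
    )


def simulate_dose_response(
    ic50: float,
    h: float,
    concentrations,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy observations of a Hill dose-response.

    The normalized response is r(c) = 1 / (1 + (c/ic50)^h) plus Gaussian
    noise, clipped to [0, 1.2]; the zero-concentration anchor is exactly
    1 (it defines the normalization).  Returns a tidy DataFrame
    (concentration, replicate, response).
    """
    if ic50 <= 0 or h <= 0:
        raise ValueError("ic50 and h must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    rng = _child_rng(seed, "dose")
    rows = []
    for conc in c:
        for rep in range(n_replicates):
            if conc == 0:
                r = 1.0
            else:
                r = 1.0 / (1.0 + (conc / ic50) ** h)
                r = float(np.clip(r + rng.normal(0.0, noise_sd), 0.0, 1.2))
            rows.append((float(conc), f"r{rep + 1}", r))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "response"])


def simulate_flow_sample(
    populations,
    n_events: int = 2000,
    seed: int = 0,
    seed_extra: int = 0,
) -> pd.DataFrame:
    """Flow-cytometry events from a mixture of log-normal populations.

    ``populations`` is a list of (fraction, FlowPopulation); fractions
    must sum to 1.  Returns a DataFrame with columns
    fsc, ssc, green, orange.
    """
    fracs = [f for f, _ in populations]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    rng = _child_rng(seed, "flow", extra=seed_extra)
    counts = rng.multinomial(n_events, fracs)
    frames = []
    for n, (_, pop) in zip(counts, populations):
        frames.append(
            pd.DataFrame(
                {
                    "fsc": rng.lognormal(pop.fsc_log_mean, pop.fsc_log_sd, n),
                    "ssc": rng.lognormal(pop.ssc_log_mean, pop.ssc_log_sd, n),
                    "green": rng.lognormal(pop.green_log_mean, pop.green_log_sd, n),
                    "orange": rng.lognormal(pop.orange_log_mean, pop.orange_log_sd, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
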