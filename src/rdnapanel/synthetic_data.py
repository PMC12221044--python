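"""Seeded generators for every input the pipeline consumes.

This module emulates the data-generating process of a two-parent
*C. elegans* recombinant inbred line (RIL) experiment built around rDNA
copy number:

* a genome model with six chromosomes, a marker map, a single terminal
  rDNA array on chromosome I (7.2 kb units), a GFP transgene linked to the
  low-copy allele, and a toxin-antitoxin incompatibility locus at 2.3 Mb
  on chromosome I;
* meiosis with an obligate crossover per chromosome (Poisson extras from
  a uniform 50 cM map), selfing with single-offspring descent, viability
  selection against one incompatibility homozygote, and selection of F2
  founders by transgene genotype;
* per-homolog rDNA copy-number drift as independent Poisson loss/gain per
  cell division;
* binned Poisson read-depth profiles in which reads from every true rDNA
  copy collapse onto the short reference rDNA span;
* COPAS flow-sorter event tables (two well-separated truncated-lognormal
  fluorescence components plus a small explicit ambiguous mass); and
* CHEF gel runs that place array fragments on a monotone size-to-distance
  curve fitted through a ladder.

Everything is reproducible given (config, seed): the same inputs and the
same ``numpy.random.Generator`` state yield bit-identical outputs.
"""

from __future__ import annotations

import bisect
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chef_sizer import ChefLadder, calibrate_ladder
from .copy_number import DepthProfile
from .ril_genotyping import GenotypeMatrix
from .stability import DriftParams

__all__ = [
    "LOW",
    "HIGH",
    "GenomeModel",
    "Haplotype",
    "LineState",
    "PanelConfig",
    "CopasFluorParams",
    "SamplingExhaustedError",
    "build_default_genome",
    "simulate_gamete",
    "self_offspring",
    "simulate_ril_panel",
    "drift_copy_number",
    "apply_bulk_drift",
    "simulate_depth_profile",
    "simulate_copas_run",
    "simulate_chef_run",
    "simulate_genotype_matrix",
    "heterozygosity",
    "write_panel_manifest",
]

LOW = "LOW"    # lab-strain parent: ~130-copy allele, carries the GFP transgene
HIGH = "HIGH"  # wild-isolate parent: ~417-copy allele, incompatibility-null

#: Default per-homolog parental rDNA copy numbers.
PARENTAL_COPIES = {LOW: 130, HIGH: 417}

#: ce11/WS-era C. elegans chromosome lengths (bp).
CHROM_LENGTHS_BP = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}


class SamplingExhaustedError(RuntimeError):
    pass


class HaplotypeStructureError(ValueError):
    pass


# --------------------------------------------------------------------------
# Genome model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Physical and genetic layout of the simulated genome.

    ``rdna_locus`` is (chromosome, start bp, reference unit count in the
    assembly, unit length bp); the array is terminal, so start plus the
    reference span equals the chromosome length. Positions are stored as
    half-open 0-based internally; writers emit 1-based coordinates.
    """

    chrom_lengths: dict
    markers: dict            # chrom -> np.ndarray of positions (bp)
    marker_cm: dict          # chrom -> np.ndarray of genetic positions (cM)
    rdna_locus: tuple        # (chrom, start, reference_unit_count, unit_length)
    incompatibility_locus: tuple  # (chrom, pos)
    transgene_locus: tuple        # (chrom, pos)
    mito_maternal: bool = True

    def __post_init__(self) -> None:
        chrom, start, units, unit_len = self.rdna_locus
        if unit_len <= 0 or units <= 0:
            raise ValueError("rDNA unit length and count must be positive")
        if start + units * unit_len != self.chrom_lengths[chrom]:
            raise ValueError("rDNA array must be terminal on its chromosome")
        for c, pos in [self.incompatibility_locus, self.transgene_locus]:
            if not 0 <= pos < self.chrom_lengths[c]:
                raise ValueError(f"locus {c}:{pos} outside chromosome bounds")
        for c, mpos in self.markers.items():
            mpos = np.asarray(mpos)
            if np.any(np.diff(mpos) <= 0):
                raise ValueError(f"marker positions on {c} must be strictly increasing")
            if mpos.size and (mpos[0] < 0 or mpos[-1] >= self.chrom_lengths[c]):
                raise ValueError(f"markers on {c} outside chromosome bounds")
            if len(self.marker_cm[c]) != mpos.size:
                raise ValueError(f"marker physical/genetic maps differ on {c}")

    @property
    def chromosomes(self) -> list:
        return list(self.chrom_lengths)

    @property
    def rdna_chrom(self) -> str:
        return self.rdna_locus[0]

    @property
    def rdna_start(self) -> int:
        return self.rdna_locus[1]

    def map_length_morgans(self, chrom: str) -> float:
        cm = self.marker_cm[chrom]
        return float(cm[-1] - cm[0]) / 100.0 if len(cm) else 0.5

    def marker_map_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for p, c in zip(self.markers[chrom], self.marker_cm[chrom]):
                rows.append(
                    {
                        "marker": f"{chrom}:{int(p) + 1}",  # 1-based marker names
                        "chrom": chrom,
                        "pos_bp": int(p),
                        "pos_cm": float(c),
                    }
                )
        return pd.DataFrame(rows)


def build_default_genome(
    markers_per_chrom: int = 500,
    reference_unit_count: int = 1,
    unit_length: int = 7200,
    transgene_pos: int = 15_000_000,
    incompatibility_pos: int = 2_300_000,
    map_length_cm: float = 50.0,
) -> GenomeModel:
    """Six-chromosome model with the cross's landmark loci on chromosome I.

    The genetic map is uniform (default 50 cM per chromosome). Markers are
    evenly spaced and, on chromosome I, stop short of the terminal rDNA
    span. The reference assembly collapses the array to
    ``reference_unit_count`` units (default a single 7.2 kb unit).

    The default transgene position sits ~65 kb (~0.2 cM under the uniform
    map) proximal to the array: recombination is strongly suppressed near
    chromosome tips in C. elegans, and this effective genetic distance
    reproduces the complete marker-array co-segregation observed in the
    cross; the physical transgene insertion lies farther left in that
    suppressed domain.
    """
    rdna_chrom = "I"
    L_I = CHROM_LENGTHS_BP[rdna_chrom]
    rdna_start = L_I - reference_unit_count * unit_length
    markers = {}
    marker_cm = {}
    for chrom, L in CHROM_LENGTHS_BP.items():
        hi = rdna_start if chrom == rdna_chrom else L
        pos = np.linspace(hi / (markers_per_chrom + 1), hi - 1, markers_per_chrom)
        markers[chrom] = np.unique(pos.astype(np.int64))
        marker_cm[chrom] = np.linspace(0.0, map_length_cm, len(markers[chrom]))
    return GenomeModel(
        chrom_lengths=dict(CHROM_LENGTHS_BP),
        markers=markers,
        marker_cm=marker_cm,
        rdna_locus=(rdna_chrom, rdna_start, reference_unit_count, unit_length),
        incompatibility_locus=(rdna_chrom, incompatibility_pos),
        transgene_locus=(rdna_chrom, transgene_pos),
    )


# --------------------------------------------------------------------------
# Haplotypes and line states
# --------------------------------------------------------------------------

@dataclass
class Haplotype:
    """One haploid genome: per chromosome, (segment end bp, parental label).

    Segments tile [0, chromosome length) with adjacent labels distinct.
    """

    segments: dict  # chrom -> list[(end, label)]

    def validate(self, genome: GenomeModel) -> None:
        for chrom, L in genome.chrom_lengths.items():
            segs = self.segments.get(chrom)
            if not segs:
                raise HaplotypeStructureError(f"no segments on {chrom}")
            prev = 0
            prev_lab = None
            for end, lab in segs:
                if end <= prev:
                    raise HaplotypeStructureError(f"non-increasing segment end on {chrom}")
                if lab == prev_lab:
                    raise HaplotypeStructureError(f"unmerged adjacent labels on {chrom}")
                prev, prev_lab = end, lab
            if prev != L:
                raise HaplotypeStructureError(
                    f"segments on {chrom} end at {prev}, expected {L}"
                )

    def label_at(self, chrom: str, pos: int) -> str:
        segs = self.segments[chrom]
        i = bisect.bisect_right([e for e, _ in segs], pos)
        return segs[min(i, len(segs) - 1)][1]

    def labels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        segs = self.segments[chrom]
        ends = np.fromiter((e for e, _ in segs), dtype=np.int64, count=len(segs))
        labs = np.array([lab for _, lab in segs])
        idx = np.searchsorted(ends, positions, side="right")
        return labs[np.minimum(idx, len(labs) - 1)]

    def n_blocks(self, chrom: str) -> int:
        return len(self.segments[chrom])

    @classmethod
    def uniform(cls, genome: GenomeModel, label: str) -> "Haplotype":
        return cls({c: [(L, label)] for c, L in genome.chrom_lengths.items()})


@dataclass
class LineState:
    """A (possibly heterozygous) worm line.

    ``rdna_copies`` is aligned with ``haplotypes``: copy count i rides on
    homolog i and is transmitted with whatever that homolog passes at the
    rDNA locus. ``transgene`` is True when at least one homolog carries the
    low-copy parent's chromosome at the transgene locus (GFP visible);
    homozygosity is exposed via ``transgene_genotype``.
    """

    haplotypes: tuple
    rdna_copies: tuple
    mito: str
    transgene: bool
    _transgene_dose: int = 0

    @classmethod
    def make(cls, haplotypes, rdna_copies, mito, genome: GenomeModel) -> "LineState":
        chrom, pos = genome.transgene_locus
        dose = sum(1 for h in haplotypes if h.label_at(chrom, pos) == LOW)
        return cls(
            haplotypes=tuple(haplotypes),
            rdna_copies=tuple(int(c) for c in rdna_copies),
            mito=mito,
            transgene=dose > 0,
            _transgene_dose=dose,
        )

    @property
    def transgene_genotype(self) -> int:
        """Number of homologs carrying the transgene (0, 1 or 2)."""
        return self._transgene_dose

    @property
    def haploid_copies(self) -> float:
        """Reported haploid copy number: mean of the two homolog counts."""
        return float(np.mean(self.rdna_copies))

    def genotype_at(self, chrom: str, pos: int) -> tuple:
        return tuple(h.label_at(chrom, pos) for h in self.haplotypes)

    def is_homozygous(self, chrom: str, pos: int, label: str) -> bool:
        g = self.genotype_at(chrom, pos)
        return g[0] == g[1] == label

    def rdna_allele_label(self, genome: GenomeModel) -> str:
        """Label at the rDNA locus (for homozygous lines, the allele class)."""
        g = self.genotype_at(genome.rdna_chrom, genome.rdna_start)
        return g[0] if g[0] == g[1] else "HET"


# --------------------------------------------------------------------------
# Meiosis and panel simulation
# --------------------------------------------------------------------------

def _splice(segs0, segs1, cuts, start_source, L):
    """Alternate between two segment lists at the cut positions."""
    sources = (
        ([e for e, _ in segs0], [lab for _, lab in segs0]),
        ([e for e, _ in segs1], [lab for _, lab in segs1]),
    )
    out_e: list = []
    out_l: list = []
    prev = 0
    cur = start_source
    for cut in [*cuts, L]:
        ends, labs = sources[cur]
        i = bisect.bisect_right(ends, prev)
        while prev < cut:
            e = min(ends[i], cut)
            lab = labs[i]
            if out_l and out_l[-1] == lab:
                out_e[-1] = e
            else:
                out_e.append(e)
                out_l.append(lab)
            prev = e
            i += 1
        cur ^= 1
    return list(zip(out_e, out_l))


def simulate_gamete(
    parent: LineState,
    genome: GenomeModel,
    rng: np.random.Generator,
    obligate_crossover: bool = True,
    validate: bool = False,
):
    """One meiotic product: a recombinant haplotype plus its rDNA copy count.

    Per chromosome the crossover count is a Poisson draw from the genetic
    map length in Morgans, forced to at least one when
    ``obligate_crossover`` (the C. elegans-like regime). Crossover
    positions are uniform in genetic position, which under the uniform map
    is uniform in bp. The transmitted rDNA copy count is that of the
    homolog contributing the segment spanning the rDNA locus.
    """
    if validate:
        for h in parent.haplotypes:
            h.validate(genome)
    h0, h1 = parent.haplotypes
    segments = {}
    copies = None
    for chrom, L in genome.chrom_lengths.items():
        k = int(rng.poisson(genome.map_length_morgans(chrom)))
        if obligate_crossover:
            k = max(1, k)
        cuts = sorted(set(int(x) for x in rng.integers(1, L, size=k)))
        start = int(rng.integers(2))
        segments[chrom] = _splice(h0.segments[chrom], h1.segments[chrom], cuts, start, L)
        if chrom == genome.rdna_chrom:
            # which source homolog contributes the terminal rDNA segment
            flips = bisect.bisect_right(cuts, genome.rdna_start)
            src = (start + flips) % 2
            copies = parent.rdna_copies[src]
    return Haplotype(segments), copies


def self_offspring(
    parent: LineState, genome: GenomeModel, rng: np.random.Generator
) -> LineState:
    """Self-fertilization: two independent gametes, maternal mitochondria."""
    ha, ca = simulate_gamete(parent, genome, rng)
    hb, cb = simulate_gamete(parent, genome, rng)
    return LineState.make((ha, hb), (ca, cb), parent.mito, genome)


@dataclass(frozen=True)
class PanelConfig:
    """RIL panel design: F1 selfing, F2 founder selection, then selfing.

    Defaults follow the published cross: 118-120 lines split evenly
    between transgene-homozygous-positive (low-copy) and homozygous-
    negative (high-copy) founders, 10 generations of single-worm selfing,
    20 further bulk generations, and viability selection in which a
    homozygote for the incompatibility-null (high-copy parent) allele born
    to a heterozygous selfing parent survives with probability 1/3.
    """

    n_lines: int = 118
    f2_split: float = 0.5
    selfing_generations: int = 10
    bulk_generations: int = 20
    incompatibility_penalty: float = 1.0 / 3.0
    seed: int = 0
    max_draws_per_line: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.f2_split <= 1.0:
            raise ValueError("f2_split must be in [0, 1]")
        if not 0.0 <= self.incompatibility_penalty <= 1.0:
            raise ValueError("incompatibility_penalty must be in [0, 1]")
        if self.selfing_generations < 0 or self.bulk_generations < 0:
            raise ValueError("generation counts must be nonnegative")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


def _surviving_self_offspring(
    parent: LineState,
    genome: GenomeModel,
    penalty: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> LineState:
    """Draw a selfed offspring subject to toxin-antitoxin viability selection.

    The toxin is delivered by heterozygous parents; offspring homozygous
    for the null (HIGH-parent) allele then survive with probability
    ``penalty``. Homozygous parents deliver no toxin.
    """
    chrom, pos = genome.incompatibility_locus
    parent_het = len(set(parent.genotype_at(chrom, pos))) == 2
    for _ in range(max_attempts):
        child = self_offspring(parent, genome, rng)
        if not parent_het:
            return child
        if child.is_homozygous(chrom, pos, HIGH) and rng.random() >= penalty:
            continue  # killed by the toxin
        return child
    raise SamplingExhaustedError("no surviving offspring after many attempts")


def simulate_ril_panel(
    config: PanelConfig,
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
    parental_copies: dict = PARENTAL_COPIES,
) -> list:
    """Simulate a RIL panel under the cross design.

    An F1 heterozygote (HIGH hermaphrodite x LOW male; maternal
    mitochondria therefore HIGH) is selfed to produce F2 founders, drawn
    under incompatibility selection and screened so that ``f2_split`` of
    the panel is transgene-homozygous-positive and the rest homozygous-
    negative. Each founder then undergoes single-offspring selfing descent
    for ``selfing_generations`` generations.

    Raises
    ------
    SamplingExhaustedError
        If a founder class cannot be filled within the bounded number of
        F2 draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f1 = LineState.make(
        (Haplotype.uniform(genome, HIGH), Haplotype.uniform(genome, LOW)),
        (parental_copies[HIGH], parental_copies[LOW]),
        mito=HIGH,
        genome=genome,
    )
    n_pos = int(round(config.n_lines * config.f2_split))
    n_neg = config.n_lines - n_pos
    founders: list = []
    budget = config.max_draws_per_line * config.n_lines
    while (n_pos > 0 or n_neg > 0) and budget > 0:
        budget -= 1
        f2 = _surviving_self_offspring(
            f1, genome, config.incompatibility_penalty, rng
        )
        if f2.transgene_genotype == 2 and n_pos > 0:
            founders.append(f2)
            n_pos -= 1
        elif f2.transgene_genotype == 0 and n_neg > 0:
            founders.append(f2)
            n_neg -= 1
    if n_pos > 0 or n_neg > 0:
        raise SamplingExhaustedError(
            f"could not satisfy f2_split: missing {n_pos} positive / {n_neg} negative"
        )
    panel = []
    for founder in founders:
        line = founder
        for _ in range(config.selfing_generations):
            line = _surviving_self_offspring(
                line, genome, config.incompatibility_penalty, rng
            )
        panel.append(line)
    return panel


def heterozygosity(line: LineState, genome: GenomeModel) -> float:
    """Fraction of map markers at which the two homologs disagree."""
    h0, h1 = line.haplotypes
    total = 0
    het = 0
    for chrom, pos in genome.markers.items():
        a = h0.labels_at(chrom, pos)
        b = h1.labels_at(chrom, pos)
        het += int(np.sum(a != b))
        total += len(pos)
    return het / total


# --------------------------------------------------------------------------
# Copy-number drift
# --------------------------------------------------------------------------

def drift_copy_number(
    copies: int, params: DriftParams, rng: np.random.Generator
) -> int:
    """Apply Poisson copy loss and gain over the parameterized divisions.

    Losses ~ Poisson(divisions * loss_rate), gains ~ Poisson(divisions *
    gain_rate); the result is floored at zero (an array cannot go
    negative).
    """
    if copies < 0:
        raise ValueError("copies must be nonnegative")
    d = params.total_divisions
    losses = int(rng.poisson(d * params.loss_rate))
    gains = int(rng.poisson(d * params.gain_rate))
    return max(0, copies - losses + gains)


def apply_bulk_drift(
    panel, params: DriftParams, rng: np.random.Generator
) -> list:
    """Drift each homolog's copy count independently; returns new LineStates."""
    out = []
    for line in panel:
        new = tuple(drift_copy_number(c, params, rng) for c in line.rdna_copies)
        out.append(replace(line, rdna_copies=new))
    return out


# --------------------------------------------------------------------------
# Depth profiles
# --------------------------------------------------------------------------

def simulate_depth_profile(
    line: LineState,
    genome: GenomeModel,
    mean_depth: float,
    bin_size: int = 1000,
    blacklist_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    chromosomes=None,
) -> DepthProfile:
    """Binned Poisson read counts for one line.

    Single-copy bins draw Poisson(mean_depth) per full bin. All reads from
    the line's true rDNA copies collapse onto the reference rDNA span, so
    rDNA bins draw Poisson(mean_depth * haploid_copies /
    reference_unit_count) per full bin. A random ``blacklist_fraction`` of
    single-copy bins is flagged blacklisted (their counts are drawn but
    must be ignored downstream). Bins are split at the rDNA boundary, so
    widths can be partial; rates scale with width.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be nonnegative")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if rng is None:
        rng = np.random.default_rng()
    u = genome.rdna_locus[2]
    c_hap = line.haploid_copies
    recs = []
    for chrom in chromosomes or genome.chromosomes:
        L = genome.chrom_lengths[chrom]
        edges = list(range(0, L, bin_size)) + [L]
        if chrom == genome.rdna_chrom and genome.rdna_start not in edges:
            edges = sorted(set(edges) | {genome.rdna_start})
        starts = np.array(edges[:-1], dtype=np.int64)
        ends = np.array(edges[1:], dtype=np.int64)
        is_rdna = (
            (starts >= genome.rdna_start)
            if chrom == genome.rdna_chrom
            else np.zeros(len(starts), dtype=bool)
        )
        widths = (ends - starts) / bin_size
        rate = np.where(is_rdna, mean_depth * c_hap / u, mean_depth) * widths
        counts = rng.poisson(rate)
        klass = np.where(is_rdna, "rdna", "single_copy").astype(object)
        if blacklist_fraction > 0:
            sc_idx = np.flatnonzero(~is_rdna)
            n_black = int(round(blacklist_fraction * sc_idx.size))
            if n_black:
                black = rng.choice(sc_idx, size=n_black, replace=False)
                klass[black] = "blacklist"
        recs.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "count": counts,
                    "region_class": klass,
                }
            )
        )
    return DepthProfile(
        bins=pd.concat(recs, ignore_index=True),
        bin_size=bin_size,
        reference_unit_count=u,
        unit_length=genome.rdna_locus[3],
    )


# --------------------------------------------------------------------------
# COPAS event tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CopasFluorParams:
    """Fluorescence mixture for COPAS events (arbitrary units).

    Component medians sit far outside the 20,000/50,000 gating band
    (GFP(+) at 200,000, GFP(-) at 5,000) so that, apart from the small
    explicit ``ambiguous_fraction``, events gate unambiguously. Components
    are truncated at the gate boundaries. ``tof_median``/``tof_sigma``
    parameterize the lognormal time-of-flight (worm size) distribution.
    """

    pos_median: float = 200_000.0
    neg_median: float = 5_000.0
    sigma: float = 0.35
    ambiguous_fraction: float = 0.001
    band_low: float = 20_000.0
    band_high: float = 50_000.0
    tof_median: float = 400.0
    tof_sigma: float = 0.25


def _truncated_lognormal(
    median: float, sigma: float, n: int, rng, low=None, high=None
) -> np.ndarray:
    mu = np.log(median)
    out = rng.lognormal(mu, sigma, size=n)
    bad = np.zeros(n, dtype=bool)
    if low is not None:
        bad |= out <= low
    if high is not None:
        bad |= out >= high
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = np.zeros(n, dtype=bool)
        if low is not None:
            bad |= out <= low
        if high is not None:
            bad |= out >= high
    return out


def simulate_copas_run(
    p_true: float,
    n_events: int,
    fluor_params: CopasFluorParams = CopasFluorParams(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one COPAS census of a mixed population.

    Each event is ambiguous with probability ``ambiguous_fraction``
    (fluorescence uniform inside the gating band); otherwise it is GFP(+)
    with probability ``p_true`` and its green peak height is drawn from
    the corresponding truncated-lognormal component. Returns a DataFrame
    (event_id, green_peak_height, time_of_flight).
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must be in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    fp = fluor_params
    amb = rng.random(n_events) < fp.ambiguous_fraction
    pos = rng.random(n_events) < p_true
    heights = np.empty(n_events)
    n_amb = int(amb.sum())
    heights[amb] = rng.uniform(fp.band_low, fp.band_high, size=n_amb)
    sel_pos = pos & ~amb
    sel_neg = ~pos & ~amb
    heights[sel_pos] = _truncated_lognormal(
        fp.pos_median, fp.sigma, int(sel_pos.sum()), rng, low=fp.band_high
    )
    heights[sel_neg] = _truncated_lognormal(
        fp.neg_median, fp.sigma, int(sel_neg.sum()), rng, high=fp.band_low
    )
    tof = rng.lognormal(np.log(fp.tof_median), fp.tof_sigma, size=n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "green_peak_height": heights,
            "time_of_flight": tof,
        }
    )


# --------------------------------------------------------------------------
# CHEF gel runs
# --------------------------------------------------------------------------

def simulate_chef_run(
    array_copy_numbers,
    ladder: ChefLadder,
    distance_noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: str = "log-linear",
    unit_length: int = 7200,
    flank_bp: float = 0.0,
) -> pd.DataFrame:
    """Migration distances for intact-array fragments on a CHEF gel.

    Fragment size is copies x unit length (plus any flank); the migration
    distance comes from the same strictly decreasing size-to-distance
    relationship the sizer would fit through the ladder (in the chosen
    mode), plus Gaussian measurement noise. Bands whose size falls outside
    the ladder's range are flagged ``out_of_range``.
    """
    if rng is None:
        rng = np.random.default_rng()
    cal = calibrate_ladder(ladder, mode=mode)
    copies = np.asarray(array_copy_numbers, dtype=float)
    sizes = copies * unit_length + flank_bp
    dist = cal.distance_at(sizes)
    if distance_noise_mm > 0:
        dist = dist + rng.normal(0.0, distance_noise_mm, size=dist.shape)
    lo, hi = ladder.sizes_bp.min(), ladder.sizes_bp.max()
    return pd.DataFrame(
        {
            "lane": np.arange(len(copies)),
            "copies_true": copies,
            "size_bp": sizes,
            "distance_mm": dist,
            "out_of_range": (sizes < lo) | (sizes > hi),
        }
    )


# --------------------------------------------------------------------------
# Genotype matrices and writers
# --------------------------------------------------------------------------

def simulate_genotype_matrix(
    panel,
    genome: GenomeModel,
    epsilon: float = 0.0,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    line_ids=None,
    max_markers: int | None = None,
) -> GenotypeMatrix:
    """Marker calls (A/B/H/N) for a panel from its true haplotypes.

    A = homozygous low-copy parent, B = homozygous high-copy parent, H =
    heterozygous. With probability ``epsilon`` an A or B call flips to the
    other parent; with probability ``missing_rate`` any call becomes N.
    ``max_markers`` evenly subsamples the genome's marker map.
    """
    if rng is None:
        rng = np.random.default_rng()
    mm = genome.marker_map_frame()
    if max_markers is not None and max_markers < len(mm):
        keep = np.linspace(0, len(mm) - 1, max_markers).astype(int)
        mm = mm.iloc[np.unique(keep)].reset_index(drop=True)
    if line_ids is None:
        line_ids = [f"RIL{i:03d}" for i in range(len(panel))]
    n_mk = len(mm)
    calls = np.empty((len(panel), n_mk), dtype=object)
    pos_by_chrom = {c: grp for c, grp in mm.groupby("chrom", sort=False)}
    for li, line in enumerate(panel):
        h0, h1 = line.haplotypes
        for chrom, grp in pos_by_chrom.items():
            pos = grp["pos_bp"].to_numpy()
            a = h0.labels_at(chrom, pos)
            b = h1.labels_at(chrom, pos)
            g = np.where(
                a == b, np.where(a == LOW, "A", "B"), "H"
            ).astype(object)
            calls[li, grp.index.to_numpy()] = g
    if epsilon > 0:
        flip = rng.random(calls.shape) < epsilon
        is_a = calls == "A"
        is_b = calls == "B"
        calls[flip & is_a] = "B"
        calls[flip & is_b] = "A"
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = "N"
    frame = pd.DataFrame(calls, index=line_ids, columns=mm["marker"])
    return GenotypeMatrix(calls=frame, marker_map=mm, epsilon=max(epsilon, 1e-3))


def write_panel_manifest(path, panel, config: PanelConfig, line_ids=None) -> None:
    """JSON manifest of the simulated truth: copies, transgene, mito, seed."""
    if line_ids is None:
        line_ids = [f"RIL{i:03d}" for i in range(len(panel))]
    payload = {
        "seed": config.seed,
        "n_lines": config.n_lines,
        "selfing_generations": config.selfing_generations,
        "bulk_generations": config.bulk_generations,
        "incompatibility_penalty": config.incompatibility_penalty,
        "lines": [
            {
                "line": lid,
                "rdna_copies": list(line.rdna_copies),
                "haploid_copies": line.haploid_copies,
                "transgene": bool(line.transgene),
                "mito": line.mito,
            }
            for lid, line in zip(line_ids, panel)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
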