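"""Haploblock inference, segregation-distortion scanning and co-segregation.

Recombinant inbred lines are essentially homozygous mosaics of the two
parental haplotypes, so noisy per-marker genotype calls are smoothed with a
two-state hidden Markov model: hidden states are the parental origins
{A, B} (A = low-copy lab-strain parent, B = high-copy wild-isolate parent),
transition probabilities between adjacent markers are Haldane recombination
fractions from the genetic map, and emissions allow a per-call error rate
epsilon. Decoding is max-marginal: each marker takes the state with the
larger forward-backward posterior, and runs of equal labels become
haploblocks with breakpoints at inter-marker midpoints.

The distortion scan asks, marker by marker, whether parental allele counts
across the panel deviate from the Mendelian 50:50 expectation (two-sided
exact binomial test, Bonferroni-corrected across markers). In this cross a
toxin-antitoxin incompatibility at 2.3 Mb on chromosome I kills a fraction
of one homozygote class, leaving a localized distortion signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "GenotypeMatrix",
    "HaploblockSet",
    "DistortionScan",
    "CosegregationResult",
    "call_haploblocks",
    "scan_segregation_distortion",
    "test_cosegregation",
    "haldane",
    "count_private_variants",
    "RDNA_PROXIMAL_HIGH_IMPACT_VARIANTS",
    "genotype_calls_from_vcf",
]

CALLS = ("A", "B", "H", "N")


def haldane(cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(cm, dtype=float) / 100.0))


@dataclass
class GenotypeMatrix:
    """Lines x markers calls with their physical/genetic map.

    ``calls``: DataFrame indexed by line id, columns = marker ids, values in
    {A, B, H, N}. ``marker_map``: DataFrame with columns marker, chrom,
    pos_bp, pos_cm, ordered by (chrom, pos_bp). ``epsilon`` is the assumed
    per-call error rate.
    """

    calls: pd.DataFrame
    marker_map: pd.DataFrame
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        need = {"marker", "chrom", "pos_bp", "pos_cm"}
        if not need <= set(self.marker_map.columns):
            raise ValueError(f"marker_map needs columns {sorted(need)}")
        if list(self.calls.columns) != list(self.marker_map["marker"]):
            raise ValueError("calls columns must match marker_map order")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"unknown genotype calls: {sorted(bad)}")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_bp"].to_numpy()) <= 0):
                raise ValueError("marker positions must be strictly increasing")

    @property
    def lines(self) -> list:
        return list(self.calls.index)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.marker_map["chrom"]))

    # --- I/O -------------------------------------------------------------

    def to_tsv(self, calls_path, map_path) -> None:
        self.calls.to_csv(calls_path, sep="\t", index_label="line")
        self.marker_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, calls_path, map_path, epsilon: float = 0.01) -> "GenotypeMatrix":
        calls = pd.read_csv(calls_path, sep="\t", index_col="line")
        marker_map = pd.read_csv(map_path, sep="\t")
        return cls(calls=calls, marker_map=marker_map, epsilon=epsilon)


@dataclass
class HaploblockSet:
    """Decoded blocks and per-marker posteriors for every line."""

    blocks: pd.DataFrame  # line, chrom, start, end, label
    posteriors: dict      # (line, chrom) -> (n_markers, 2) array, cols (A, B)
    marker_map: pd.DataFrame

    def blocks_for(self, line, chrom) -> pd.DataFrame:
        b = self.blocks
        return b[(b["line"] == line) & (b["chrom"] == chrom)].reset_index(drop=True)

    def labels_for(self, line, chrom) -> np.ndarray:
        post = self.posteriors[(line, chrom)]
        lab = np.where(post[:, 0] >= post[:, 1], "A", "B")
        # re-apply the tie rule so labels match the decoded blocks exactly
        prev = "A"
        for i in range(len(lab)):
            if post[i, 0] == post[i, 1]:
                lab[i] = prev
            prev = lab[i]
        return lab

    def to_bed(self, path) -> None:
        out = self.blocks.copy()
        out = out[["chrom", "start", "end", "line", "label"]]
        out.to_csv(path, sep="\t", index=False, header=False)


def _forward_backward(
    obs: np.ndarray, r: np.ndarray, epsilon: float
) -> np.ndarray:
    """Scaled forward-backward posteriors for one chromosome of one line.

    obs: integer codes (0=A, 1=B, 2=uninformative). r: recombination
    fractions between adjacent markers. Returns (n, 2) posterior matrix.
    H and N calls are emitted with equal likelihood from either state, so
    they carry no information but keep the chain's length and spacing.
    """
    n = obs.size
    # emission likelihood e[i, state]
    e = np.ones((n, 2), dtype=float)
    is_a = obs == 0
    is_b = obs == 1
    e[is_a, 0] = 1.0 - epsilon
    e[is_a, 1] = epsilon
    e[is_b, 0] = epsilon
    e[is_b, 1] = 1.0 - epsilon

    fwd = np.empty((n, 2))
    scale = np.empty(n)
    fwd[0] = 0.5 * e[0]
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for i in range(1, n):
        stay = 1.0 - r[i - 1]
        pred0 = fwd[i - 1, 0] * stay + fwd[i - 1, 1] * r[i - 1]
        pred1 = fwd[i - 1, 0] * r[i - 1] + fwd[i - 1, 1] * stay
        fwd[i, 0] = pred0 * e[i, 0]
        fwd[i, 1] = pred1 * e[i, 1]
        scale[i] = fwd[i].sum()
        fwd[i] /= scale[i]

    bwd = np.empty((n, 2))
    bwd[-1] = 1.0
    for i in range(n - 2, -1, -1):
        stay = 1.0 - r[i]
        b0 = bwd[i + 1, 0] * e[i + 1, 0]
        b1 = bwd[i + 1, 1] * e[i + 1, 1]
        bwd[i, 0] = stay * b0 + r[i] * b1
        bwd[i, 1] = r[i] * b0 + stay * b1
        bwd[i] /= bwd[i].sum()

    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post


def call_haploblocks(
    gm: GenotypeMatrix,
    r_fn=None,
    epsilon: float | None = None,
    het_policy: str = "error-mass",
    chrom_lengths: dict | None = None,
) -> HaploblockSet:
    """Two-state HMM haploblock calls with max-marginal decoding.

    Parameters
    ----------
    r_fn : callable, optional
        Maps an array of inter-marker cM distances to recombination
        fractions; default Haldane.
    epsilon : float, optional
        Per-call error rate; defaults to ``gm.epsilon``.
    het_policy : {"error-mass", "drop"}
        How to treat H calls in inbred lines. Both policies make an H
        uninformative to the two-state chain (its error mass splits equally
        between the A and B emissions); "drop" additionally excludes H from
        downstream informative-call counts.
    chrom_lengths : dict, optional
        chromosome -> length bp; terminal blocks extend to [0, length).
        Without it, blocks span the marker extent of each chromosome.

    Ties in the posterior are broken toward the previous marker's label
    (toward A at the first marker). An all-missing chromosome yields one
    block labelled by the uniform prior tie rule (A) with a warning.
    """
    if epsilon is None:
        epsilon = gm.epsilon
    if het_policy not in ("error-mass", "drop"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if r_fn is None:
        r_fn = haldane

    code = {"A": 0, "B": 1, "H": 2, "N": 2}
    block_rows = []
    posteriors: dict = {}
    mm = gm.marker_map.reset_index(drop=True)
    all_calls = gm.calls.to_numpy()
    coded = np.vectorize(code.get, otypes=[int])(all_calls)
    for chrom, cmap in mm.groupby("chrom", sort=False):
        idx = cmap.index.to_numpy()
        pos = cmap["pos_bp"].to_numpy(dtype=float)
        cm = cmap["pos_cm"].to_numpy(dtype=float)
        r = np.clip(r_fn(np.diff(cm)), 1e-12, 0.5)
        length = None if chrom_lengths is None else chrom_lengths.get(chrom)
        start0 = 0.0 if length is not None else pos[0]
        end0 = float(length) if length is not None else pos[-1]
        mids = (pos[:-1] + pos[1:]) / 2.0
        for li, line in enumerate(gm.lines):
            obs = coded[li, idx]
            if np.all(obs == 2):
                warnings.warn(
                    f"line {line!r} chromosome {chrom!r} has no informative calls; "
                    "assigning a single block by the uniform prior",
                    stacklevel=2,
                )
            post = _forward_backward(obs, r, epsilon)
            posteriors[(line, chrom)] = post
            labels = []
            prev = "A"
            for i in range(len(obs)):
                if post[i, 0] > post[i, 1]:
                    lab = "A"
                elif post[i, 1] > post[i, 0]:
                    lab = "B"
                else:
                    lab = prev
                labels.append(lab)
                prev = lab
            # runs -> blocks with midpoint breakpoints
            run_start = start0
            for i in range(1, len(labels)):
                if labels[i] != labels[i - 1]:
                    block_rows.append(
                        {
                            "line": line,
                            "chrom": chrom,
                            "start": int(run_start),
                            "end": int(mids[i - 1]),
                            "label": labels[i - 1],
                        }
                    )
                    run_start = mids[i - 1]
            block_rows.append(
                {
                    "line": line,
                    "chrom": chrom,
                    "start": int(run_start),
                    "end": int(end0),
                    "label": labels[-1],
                }
            )
    return HaploblockSet(
        blocks=pd.DataFrame(block_rows), posteriors=posteriors, marker_map=mm.copy()
    )


@lru_cache(maxsize=4096)
def _binom_pvalue(k: int, n: int) -> float:
    return float(binomtest(k, n, 0.5, alternative="two-sided").pvalue)


@dataclass
class DistortionScan:
    table: pd.DataFrame           # marker, chrom, pos_bp, n_informative, freq_A, p_value, flagged
    excluded_markers: list
    n_tested: int
    alpha: float


def scan_segregation_distortion(
    gm: GenotypeMatrix, alpha: float = 0.05, count_het: bool = False
) -> DistortionScan:
    """Exact binomial test of A-allele frequency against 0.5 at every marker.

    Markers with fewer than 2 informative (A or B) lines are excluded and
    reported. A marker is flagged when p <= alpha / M with M the number of
    markers actually tested (Bonferroni).
    """
    calls = gm.calls.to_numpy()
    n_a = (calls == "A").sum(axis=0)
    n_b = (calls == "B").sum(axis=0)
    if count_het:
        # an H contributes half an observation to each side; rounded down
        n_h = (calls == "H").sum(axis=0)
        n_a = n_a + n_h // 2
        n_b = n_b + n_h // 2
    n_inf = n_a + n_b
    tested = n_inf >= 2
    m = int(tested.sum())
    rows = []
    excluded = []
    for j, mk in enumerate(gm.marker_map.itertuples()):
        if not tested[j]:
            excluded.append(mk.marker)
            continue
        p = _binom_pvalue(int(n_a[j]), int(n_inf[j]))
        rows.append(
            {
                "marker": mk.marker,
                "chrom": mk.chrom,
                "pos_bp": mk.pos_bp,
                "n_informative": int(n_inf[j]),
                "freq_A": n_a[j] / n_inf[j],
                "p_value": p,
                "flagged": bool(m > 0 and p <= alpha / m),
            }
        )
    return DistortionScan(
        table=pd.DataFrame(rows), excluded_markers=excluded, n_tested=m, alpha=alpha
    )


@dataclass(frozen=True)
class CosegregationResult:
    concordance: float
    table: pd.DataFrame  # 2x2: transgene +/- x allele class LOW/HIGH


def test_cosegregation(transgene_calls, allele_classes) -> CosegregationResult:
    """Concordance between GFP-transgene presence and the LOW rDNA allele.

    The transgene sits on the low-copy parent's chromosome I, so perfect
    linkage predicts transgene(+) <-> LOW in every line.
    """
    tg = list(transgene_calls)
    ac = list(allele_classes)
    if len(tg) != len(ac):
        raise ValueError("transgene and allele-class vectors differ in length")
    if len(tg) == 0:
        raise ValueError("empty input")
    tab = pd.crosstab(
        pd.Series(tg, name="transgene"), pd.Series(ac, name="allele_class")
    ).reindex(index=[True, False], columns=["LOW", "HIGH"], fill_value=0)
    concordant = sum(
        1 for t, a in zip(tg, ac) if (t and a == "LOW") or (not t and a == "HIGH")
    )
    return CosegregationResult(concordance=concordant / len(tg), table=tab)


# --- rDNA-proximal variant bookkeeping ----------------------------------

#: Published high-impact missense variants in the ~1.5 Mb proximal to the
#: rDNA, by wild isolate carrying them (two rows share position 14488002:
#: one substitution hits two annotated isoforms).
RDNA_PROXIMAL_HIGH_IMPACT_VARIANTS = pd.DataFrame(
    [
        ("W04A4.6", "79V>79A", 13687336, ("RC301",)),
        ("Y105E8A.32", "50R>50L", 14378647, ("MY1",)),
        ("ekl-4", "233R>233K", 14470756, ("MY1",)),
        ("Y105E8A.20", "305S>305L", 14488002, ("MY1",)),
        ("Y105E8A.20", "423S>423L", 14488002, ("MY1",)),
        ("tag-4", "213R>213W", 14989978, ("MY1", "RC301")),
        ("F31C3.3", "377R>377Q", 15049340, ("MY1",)),
    ],
    columns=["gene", "amino_acid", "pos_bp", "isolates"],
)


def count_private_variants(
    variants: pd.DataFrame | None = None,
    isolate: str = "MY1",
    exclude_shared_with: str = "RC301",
) -> int:
    """Count variant positions private to one isolate.

    Rows sharing a base-pair position are collapsed to one variant (a
    single substitution annotated against several isoforms), and positions
    also carried by ``exclude_shared_with`` are dropped.
    """
    if variants is None:
        variants = RDNA_PROXIMAL_HIGH_IMPACT_VARIANTS
    by_pos: dict[int, set] = {}
    for rec in variants.itertuples():
        iso = rec.isolates
        if isinstance(iso, str):
            iso = tuple(x.strip() for x in iso.split(","))
        by_pos.setdefault(int(rec.pos_bp), set()).update(iso)
    return sum(
        1
        for isos in by_pos.values()
        if isolate in isos and exclude_shared_with not in isos
    )


# --- VCF ingestion -------------------------------------------------------

def genotype_calls_from_vcf(path, line: str | None = None) -> pd.DataFrame:
    """Read biallelic parental-diagnostic sites from a per-line VCF.

    Sites homozygous-reference become A (lab-strain parent), homozygous-alt
    B (wild-isolate parent), heterozygous H, missing N. Returns a DataFrame
    (marker, chrom, pos_bp, call); build a GenotypeMatrix by combining
    per-line tables on a shared marker map.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if line is None:
        if len(samples) != 1:
            raise ValueError("VCF has multiple samples; pass line=<sample>")
        si = 0
    else:
        si = samples.index(line)
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = var.genotypes[si]
        alleles = gt[:2]
        if -1 in alleles:
            call = "N"
        elif alleles[0] == alleles[1]:
            call = "A" if alleles[0] == 0 else "B"
        else:
            call = "H"
        rows.append(
            {
                "marker": f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos_bp": var.POS,
                "call": call,
            }
        )
    return pd.DataFrame(rows)
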