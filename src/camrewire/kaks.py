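"""Pairwise Ka/Ks estimation and sliding-window positive-selection scanning.

The estimator is Nei–Gojobori (1986) pathway counting with a Jukes–Cantor
multiple-hit correction: synonymous and nonsynonymous *sites* are counted per
codon by classifying all nine single-nucleotide mutants, and *differences*
between two codons are partitioned by averaging over all minimal mutational
pathways, skipping pathways that pass through stop codons whenever an
alternative exists.  Ka/Ks > 1 over a region of a gene is the signature of
positive (diversifying) selection on that region.

Regions are scanned with a sliding window (default 50 codons, step 1) and a
run of consecutive windows with Ka/Ks > 1 is tested against the neutral null
Ka = Ks with a one-sided one-sample t-test on the per-window (Ka - Ks)
differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CodonAlignment",
    "KaKsEstimate",
    "KaKsProfile",
    "PositiveRegion",
    "GeneSetLabel",
    "strip_gaps",
    "ng86_sites",
    "ng86_diffs",
    "kaks_global",
    "sliding_profile",
    "call_regions",
    "classify_comparisons",
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: Mapping[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(GENETIC_CODE))
_BASES = "ACGT"
_GAP_CHARS = frozenset("-.")


class SaturationError(ValueError):
    """Raised when a substitution proportion is too large to correct."""


# ---------------------------------------------------------------------------
# alignment container


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame, gap-free pair of codon sequences for one ortholog pair."""

    gene_id: str
    species_a: str
    species_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(
                f"{self.gene_id}: sequence lengths differ ({len(a)} vs {len(b)})"
            )
        if len(a) % 3:
            raise ValueError(f"{self.gene_id}: length {len(a)} not divisible by 3")
        for seq, sp in ((a, self.species_a), (b, self.species_b)):
            bad = set(seq) - set(_BASES)
            if bad:
                raise ValueError(f"{self.gene_id}/{sp}: invalid characters {sorted(bad)}")
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError(
                        f"{self.gene_id}/{sp}: internal stop codon at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def strip_gaps(
    gene_id: str,
    species_a: str,
    species_b: str,
    aligned_a: str,
    aligned_b: str,
) -> CodonAlignment:
    """Remove every codon column containing a gap in either sequence.

    The input must be an in-frame alignment of equal length divisible by 3;
    gaps breaking the reading frame (a codon mixing gap and base characters)
    are rejected rather than silently repaired.
    """
    a, b = aligned_a.upper(), aligned_b.upper()
    if len(a) != len(b):
        raise ValueError(f"{gene_id}: aligned lengths differ")
    if len(a) % 3:
        raise ValueError(f"{gene_id}: aligned length {len(a)} not divisible by 3")
    kept_a, kept_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        gapped = _GAP_CHARS & (set(ca) | set(cb))
        if gapped:
            if (set(ca) - _GAP_CHARS and set(ca) & _GAP_CHARS) or (
                set(cb) - _GAP_CHARS and set(cb) & _GAP_CHARS
            ):
                raise ValueError(
                    f"{gene_id}: frame-breaking gap in codon column {i // 3}"
                )
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    return CodonAlignment(gene_id, species_a, species_b, "".join(kept_a), "".join(kept_b))


# ---------------------------------------------------------------------------
# NG86 counting


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon!r}")
    return codon


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the nine single-nucleotide mutants contributes 1/3 of a site:
    synonymous if the amino acid is preserved, nonsynonymous otherwise
    (mutants creating a stop codon count as nonsynonymous).  The pair always
    sums to 3.
    """
    codon = _check_sense(codon)
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE.get(mut) == aa:
                syn += 1
    return syn / 3.0, (9 - syn) / 3.0


def _pathway_steps(codon_a: str, codon_b: str) -> tuple[float, float]:
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []  # (syn, nonsyn) per stop-free pathway
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        has_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                has_stop = True
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nonsyn += 1  # a step into/out of a stop changes the protein
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not has_stop:
            valid.append((syn, nonsyn))
    pool = valid if valid else all_paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two sense codons.

    Averages over all minimal mutational pathways; pathways through stop
    codons are excluded unless every pathway passes through a stop, in which
    case all pathways are used (the step into a stop counted nonsynonymous).
    Symmetric; components sum to the nucleotide Hamming distance.
    """
    codon_a, codon_b = _check_sense(codon_a), _check_sense(codon_b)
    key = (codon_a, codon_b) if codon_a <= codon_b else (codon_b, codon_a)
    hit = _DIFF_CACHE.get(key)
    if hit is None:
        hit = _pathway_steps(key[0], key[1])
        _DIFF_CACHE[key] = hit
    return hit


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class KaKsEstimate:
    """NG86 counts and Jukes–Cantor-corrected Ka, Ks for one alignment/window."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ks: float | None
    ka: float | None
    saturated: bool = False

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; None when undefined (Ks is 0 or the estimate is saturated)."""
        if self.saturated or self.ka is None or not self.ks:
            return None
        return self.ka / self.ks


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); None when saturated."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _per_codon_counts(aln: CodonAlignment) -> np.ndarray:
    """(L, 4) array of per-codon [syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs].

    Sites are the mean of the two sequences' codons, so column sums reproduce
    the alignment-level NG86 counts; all four columns are additive over codons,
    which lets sliding windows be assembled from cumulative sums.
    """
    out = np.empty((aln.n_codons, 4))
    for i, (ca, cb) in enumerate(aln.codons()):
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        sd, nd = ng86_diffs(ca, cb)
        out[i] = ((sa + sb) / 2.0, (na + nb) / 2.0, sd, nd)
    return out


def _estimate_from_counts(s: float, n: float, sd: float, nd: float) -> KaKsEstimate:
    ps = sd / s if s > 0 else 0.0
    pn = nd / n if n > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = ks is None or ka is None
    return KaKsEstimate(s, n, sd, nd, ks, ka, saturated=saturated)


def kaks_global(aln: CodonAlignment) -> KaKsEstimate:
    """Whole-alignment NG86 Ka/Ks with Jukes–Cantor correction."""
    counts = _per_codon_counts(aln).sum(axis=0)
    return _estimate_from_counts(*counts)


@dataclass
class KaKsProfile:
    """Per-window Ka/Ks along one gene; window starts are 0-based codon indices."""

    gene_id: str
    window: int
    step: int
    n_codons: int
    windows: list[tuple[int, KaKsEstimate]] = field(default_factory=list)

    def ratios(self) -> list[float | None]:
        return [est.ratio for _, est in self.windows]


def sliding_profile(aln: CodonAlignment, window: int = 50, step: int = 1) -> KaKsProfile:
    """Sliding-window Ka/Ks profile (default 50-codon window, 1-codon step).

    Raises ``ValueError`` for genes shorter than one window; such genes yield
    no profile and are reported as too short by callers.
    """
    L = aln.n_codons
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > L:
        raise ValueError(
            f"{aln.gene_id}: gene too short ({L} codons) for a {window}-codon window"
        )
    per = _per_codon_counts(aln)
    csum = np.vstack([np.zeros(4), np.cumsum(per, axis=0)])
    prof = KaKsProfile(aln.gene_id, window, step, L)
    for start in range(0, L - window + 1, step):
        s, n, sd, nd = csum[start + window] - csum[start]
        prof.windows.append((start, _estimate_from_counts(s, n, sd, nd)))
    return prof


# ---------------------------------------------------------------------------
# region calling


@dataclass(frozen=True)
class PositiveRegion:
    """A run of sliding windows with Ka/Ks > 1, tested against Ka = Ks."""

    gene_id: str
    comparison: str
    start_codon: int  # 0-based, inclusive
    end_codon: int  # 0-based, exclusive
    n_windows: int
    mean_ratio: float
    p_value: float
    significant: bool
    degenerate_variance: bool = False


def call_regions(
    profile: KaKsProfile,
    comparison: str = "",
    min_run: int = 25,
    alpha: float = 0.05,
) -> list[PositiveRegion]:
    """Call positive-selection regions from a sliding-window profile.

    Maximal runs of at least ``min_run`` consecutive windows whose Ka/Ks is
    defined and > 1 become candidate regions.  Each region's one-sided
    one-sample t-test asks whether the per-window (Ka - Ks) mean exceeds 0;
    p < ``alpha`` flags the region significant.  A zero-variance run gets
    p = 0 when its constant (Ka - Ks) is positive (flagged degenerate),
    p = 1 otherwise.  Windows with undefined ratio break runs.
    """
    regions: list[PositiveRegion] = []
    run: list[tuple[int, KaKsEstimate]] = []

    def flush() -> None:
        if len(run) < min_run:
            return
        diffs = np.array([est.ka - est.ks for _, est in run])
        ratios = np.array([est.ratio for _, est in run])
        degenerate = bool(np.allclose(diffs, diffs[0]))
        if degenerate:
            p = 0.0 if diffs[0] > 0 else 1.0
        else:
            p = float(stats.ttest_1samp(diffs, 0.0, alternative="greater").pvalue)
        start = run[0][0]
        end = run[-1][0] + profile.window
        regions.append(
            PositiveRegion(
                gene_id=profile.gene_id,
                comparison=comparison,
                start_codon=start,
                end_codon=end,
                n_windows=len(run),
                mean_ratio=float(ratios.mean()),
                p_value=p,
                significant=p < alpha,
                degenerate_variance=degenerate,
            )
        )

    for start, est in profile.windows:
        r = est.ratio
        if r is not None and r > 1.0:
            run.append((start, est))
        else:
            flush()
            run = []
    flush()
    return regions


# ---------------------------------------------------------------------------
# gene-set classification (comparison sets 1a / 1b)


@dataclass(frozen=True)
class GeneSetLabel:
    gene_id: str
    label: str  # "set_1a" | "set_1b" | "none"


def classify_comparisons(
    gene_id: str,
    regions_by_comparison: Mapping[str, Sequence[PositiveRegion]],
    c3_comparisons: Iterable[str],
    c4_comparisons: Iterable[str],
    require_significant: bool = True,
) -> GeneSetLabel:
    """Assign a gene to comparison set 1a, 1b or none.

    Set 1a: a positive region in *every* comparison (all C3 and all C4
    pairings).  Set 1b: a positive region in every C3 comparison and in *no*
    C4 comparison.  A gene missing any comparison is unclassifiable (none).
    With ``require_significant=False`` a region merely needs Ka/Ks > 1 runs,
    not t-test significance.
    """
    c3 = list(c3_comparisons)
    c4 = list(c4_comparisons)
    needed = c3 + c4
    if any(c not in regions_by_comparison for c in needed):
        return GeneSetLabel(gene_id, "none")

    def hit(comp: str) -> bool:
        regs = regions_by_comparison[comp]
        if require_significant:
            return any(r.significant for r in regs)
        return len(regs) > 0

    c3_hits = [hit(c) for c in c3]
    c4_hits = [hit(c) for c in c4]
    if all(c3_hits) and all(c4_hits):
        return GeneSetLabel(gene_id, "set_1a")
    if all(c3_hits) and not any(c4_hits):
        return GeneSetLabel(gene_id, "set_1b")
    return GeneSetLabel(gene_id, "none")
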