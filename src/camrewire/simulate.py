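"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators mirror the four analysis inputs:

* codon-pair alignments diverged under a region-specific dN/dS (``omega``)
  along the gene, for calibrating the sliding-window Ka/Ks scan;
* diel ortholog expression pairs — a cosine with a gene-specific peak phase
  sampled on each species' own grid plus i.i.d. Gaussian noise — for the
  phase-shift classifier;
* ortholog tables with a prescribed clade structure for the partitioner;
* module memberships with a planted enriched gene set for the Poisson
  over-representation test.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clades import PHOTOSYNTHESIS_TYPES, OrthologGroup
from .diel import (
    AGAVE_GRID,
    ARABIDOPSIS_GRID,
    DielSeries,
    phase_bin,
)
from .kaks import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, CodonAlignment

__all__ = [
    "OmegaMap",
    "DielTruth",
    "CladeSpec",
    "PlantedEnrichment",
    "simulate_codon_pair",
    "simulate_diel_pair",
    "simulate_ortholog_table",
    "simulate_module_membership",
    "shift_class_of_peaks",
]

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# codon-pair simulation


@dataclass(frozen=True)
class OmegaMap:
    """Piecewise-constant dN/dS along a gene, tiling [0, L) in codon units."""

    segments: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty omega map")
        prev_end = self.segments[0][0]
        if prev_end != 0:
            raise ValueError("omega map must start at codon 0")
        for start, end, omega in self.segments:
            if start != prev_end:
                raise ValueError(f"segments must tile without gaps at codon {start}")
            if end <= start:
                raise ValueError(f"empty segment [{start}, {end})")
            if omega < 0:
                raise ValueError("omega must be nonnegative")
            prev_end = end

    @property
    def length(self) -> int:
        return self.segments[-1][1]

    def omega_at(self, codon_index: int) -> float:
        for start, end, omega in self.segments:
            if start <= codon_index < end:
                return omega
        raise IndexError(codon_index)

    @classmethod
    def uniform(cls, length: int, omega: float) -> "OmegaMap":
        return cls(((0, length, omega),))

    @classmethod
    def planted(
        cls, length: int, start: int, end: int, omega_in: float, omega_out: float
    ) -> "OmegaMap":
        """Background ``omega_out`` with ``omega_in`` planted on [start, end)."""
        segs = []
        if start > 0:
            segs.append((0, start, omega_out))
        segs.append((start, end, omega_in))
        if end < length:
            segs.append((end, length, omega_out))
        return cls(tuple(segs))


def _codon_moves(codon: str) -> list[tuple[str, bool, bool]]:
    """All single-nucleotide moves to sense codons: (target, is_ts, is_syn)."""
    moves = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            tgt = codon[:pos] + base + codon[pos + 1 :]
            if tgt in STOP_CODONS:
                continue  # proposals creating stops are rejected outright
            moves.append(
                (
                    tgt,
                    (codon[pos], base) in _TRANSITIONS,
                    GENETIC_CODE[codon] == GENETIC_CODE[tgt],
                )
            )
    return moves


_MOVES = {c: _codon_moves(c) for c in SENSE_CODONS}


def _rate_scale(kappa: float) -> float:
    """Mean total substitution rate over the 61 sense codons at omega = 1.

    Used as the normalizer so that ``branch_length`` is the expected number
    of substitutions per codon for a neutral (omega = 1) gene.
    """
    total = 0.0
    for codon in SENSE_CODONS:
        total += sum(kappa if ts else 1.0 for _, ts, _ in _MOVES[codon])
    return total / len(SENSE_CODONS)


_RATE_CACHE: dict[tuple[str, float, float], tuple[list[str], np.ndarray, float]] = {}


def _rates_for(codon: str, omega: float, kappa: float, scale: float):
    key = (codon, omega, kappa)
    hit = _RATE_CACHE.get(key)
    if hit is None:
        targets = [tgt for tgt, _, _ in _MOVES[codon]]
        rates = np.array(
            [
                (kappa if ts else 1.0) * (1.0 if syn else omega)
                for _, ts, syn in _MOVES[codon]
            ]
        ) / scale
        hit = (targets, rates, float(rates.sum()))
        _RATE_CACHE[key] = hit
    return hit


def _evolve_codon(
    codon: str, omega: float, t: float, kappa: float, scale: float, rng: np.random.Generator
) -> str:
    """Gillespie simulation of one codon over branch length ``t``."""
    clock = 0.0
    while True:
        targets, rates, total = _rates_for(codon, omega, kappa, scale)
        if total <= 0:
            return codon  # omega = 0 codon with no synonymous neighbours
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            return codon
        codon = targets[rng.choice(len(rates), p=rates / total)]


def simulate_codon_pair(
    length_codons: int,
    omega_map: OmegaMap,
    branch_length: float,
    kappa: float = 2.0,
    seed: int = 0,
    gene_id: str = "sim",
    species_a: str = "spA",
    species_b: str = "spB",
) -> tuple[CodonAlignment, OmegaMap]:
    """Evolve two descendants of a random ancestor under a codon process.

    The ancestor is drawn uniformly from the 61 sense codons per position and
    each descendant evolves independently along a branch of length
    ``branch_length / 2``, so the pair's expected divergence is
    ``branch_length`` (expected substitutions per codon at omega = 1).
    Proposals are HKY-style single-nucleotide changes (transition:transversion
    ratio ``kappa``) accepted at relative rate 1 if synonymous, ``omega`` if
    nonsynonymous, 0 if they would create a stop codon.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if branch_length < 0:
        raise ValueError("branch_length must be nonnegative")
    if omega_map.length != length_codons:
        raise ValueError(
            f"omega map covers [0, {omega_map.length}), gene has {length_codons} codons"
        )
    rng = np.random.default_rng(seed)
    scale = _rate_scale(kappa)
    half = branch_length / 2.0
    seq_a, seq_b = [], []
    for i in range(length_codons):
        anc = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        omega = omega_map.omega_at(i)
        seq_a.append(_evolve_codon(anc, omega, half, kappa, scale, rng))
        seq_b.append(_evolve_codon(anc, omega, half, kappa, scale, rng))
    aln = CodonAlignment(gene_id, species_a, species_b, "".join(seq_a), "".join(seq_b))
    return aln, omega_map


# ---------------------------------------------------------------------------
# diel expression pairs


def shift_class_of_peaks(peak_a: float, peak_b: float) -> str:
    """Shift class implied by true peak phases under the standard bins."""
    bin_a, bin_b = phase_bin(peak_a), phase_bin(peak_b)
    if bin_b == "morning" and bin_a in ("early_night", "late_night"):
        return "morning_to_night"
    if bin_b == "afternoon" and bin_a == "late_night":
        return "afternoon_to_night"
    return "none"


@dataclass(frozen=True)
class DielTruth:
    """Ground truth for one simulated ortholog expression pair."""

    pair_id: str
    peak_a: float  # CAM species peak phase, hours after lights-on
    peak_b: float  # C3 reference peak phase
    amplitude: float = 1.0
    noise_sd: float = 0.3
    true_shift_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.peak_a < 24 and 0 <= self.peak_b < 24):
            raise ValueError("peak phases must lie in [0, 24)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        implied = shift_class_of_peaks(self.peak_a, self.peak_b)
        if not self.true_shift_class:
            object.__setattr__(self, "true_shift_class", implied)
        elif self.true_shift_class != implied:
            raise ValueError(
                f"{self.pair_id}: declared class {self.true_shift_class!r} "
                f"inconsistent with peaks (implied {implied!r})"
            )


def simulate_diel_pair(
    truth: DielTruth,
    grid_a: Sequence[float] = AGAVE_GRID,
    grid_b: Sequence[float] = ARABIDOPSIS_GRID,
    seed: int = 0,
) -> tuple[DielSeries, DielSeries]:
    """Sample a cosine diel course for each species on its own grid.

    Value at time t is ``amplitude * cos(2*pi*(t - peak)/24) + N(0, noise_sd)``,
    i.i.d. across grid points; species a (CAM) uses ``peak_a``, species b
    (C3 reference) ``peak_b``.
    """
    rng = np.random.default_rng(seed)

    def sample(grid: Sequence[float], peak: float, gene: str, species: str) -> DielSeries:
        t = np.asarray(grid, float)
        mean = truth.amplitude * np.cos(2 * np.pi * (t - peak) / 24.0)
        vals = mean + rng.normal(0.0, truth.noise_sd, t.size)
        return DielSeries(gene, species, tuple(t), tuple(float(v) for v in vals))

    a = sample(grid_a, truth.peak_a, f"{truth.pair_id}_a", "cam")
    b = sample(grid_b, truth.peak_b, f"{truth.pair_id}_b", "c3")
    return a, b


# ---------------------------------------------------------------------------
# ortholog tables


@dataclass(frozen=True)
class CladeSpec:
    """Requested clade composition for a simulated ortholog table.

    ``roster`` maps species to photosynthesis type; ``clade_counts`` maps a
    clade label (e.g. ``"C3:CAM:C4"`` or ``"CAM-only"``) to the number of
    groups to generate; member counts per species are uniform on
    [1, ``max_genes_per_species``].
    """

    roster: Mapping[str, str]
    clade_counts: Mapping[str, int]
    max_genes_per_species: int = 3

    def types_of(self, label: str) -> tuple[str, ...]:
        if label.endswith("-only"):
            types: tuple[str, ...] = (label[: -len("-only")],)
        else:
            types = tuple(label.split(":"))
        for t in types:
            if t not in PHOTOSYNTHESIS_TYPES:
                raise ValueError(f"unknown type {t!r} in clade label {label!r}")
            if t not in self.roster.values():
                raise ValueError(f"clade {label!r} needs type {t!r}, absent from roster")
        return types


def simulate_ortholog_table(spec: CladeSpec, seed: int = 0) -> list[OrthologGroup]:
    """Generate ortholog groups whose clade labels match ``spec`` exactly.

    For every requested clade, each group receives at least one species of
    every type in the label (guaranteeing the label) and never a species of
    any other type.
    """
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    for sp, t in spec.roster.items():
        by_type.setdefault(t, []).append(sp)
    groups: list[OrthologGroup] = []
    gene_counter = 0
    for label in sorted(spec.clade_counts):
        n_groups = spec.clade_counts[label]
        types = spec.types_of(label)
        for i in range(n_groups):
            members: dict[str, tuple[str, ...]] = {}
            for t in types:
                pool = sorted(by_type[t])
                n_sp = int(rng.integers(1, len(pool) + 1))
                chosen = rng.choice(len(pool), size=n_sp, replace=False)
                for idx in sorted(chosen):
                    sp = pool[idx]
                    n_genes = int(rng.integers(1, spec.max_genes_per_species + 1))
                    genes = tuple(
                        f"g{gene_counter + k:06d}" for k in range(n_genes)
                    )
                    gene_counter += n_genes
                    members[sp] = genes
            if sum(len(g) for g in members.values()) < 2:
                sp = next(iter(members))
                members[sp] = members[sp] + (f"g{gene_counter:06d}",)
                gene_counter += 1
            groups.append(OrthologGroup(f"OG{len(groups):05d}", members))
    return groups


# ---------------------------------------------------------------------------
# module membership with planted enrichment


@dataclass(frozen=True)
class PlantedEnrichment:
    set_id: str
    module_id: str
    set_size: int
    fold_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be nonnegative")
        if self.set_size < 0:
            raise ValueError("set_size must be nonnegative")


def simulate_module_membership(
    n_genes: int,
    module_sizes: Mapping[str, int],
    planted: PlantedEnrichment,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, list[str]], list[str]]:
    """Random module assignment with one gene set planted at a target fold.

    Modules take their stated sizes; leftover genes form the unassigned
    remainder (the "Non-module" row of enrichment tables).  ``fold_enrichment``
    is the target observed/expected ratio of the set's overlap with the
    planted module: the overlap count is drawn from Fisher's noncentral
    hypergeometric distribution (the biased-urn model) with its odds solved
    so the mean overlap equals ``fold * |set| * |module| / n_genes``, then
    set members are drawn uniformly within and outside the module.  At
    ``fold_enrichment = 1`` this reduces exactly to a uniform draw of the
    whole set.

    Returns (membership, gene_sets, universe).
    """
    total_in_modules = sum(module_sizes.values())
    if total_in_modules > n_genes:
        raise ValueError("module sizes exceed the universe")
    if planted.module_id not in module_sizes:
        raise ValueError(f"planted module {planted.module_id!r} not in module_sizes")
    if planted.set_size > n_genes:
        raise ValueError("planted set larger than the universe")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:06d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    membership: dict[str, str] = {}
    pos = 0
    for module_id in sorted(module_sizes):
        for k in range(module_sizes[module_id]):
            membership[universe[order[pos]]] = module_id
            pos += 1
    s, m = planted.set_size, module_sizes[planted.module_id]
    if s == 0:
        return membership, {planted.set_id: []}, universe
    if planted.fold_enrichment == 1.0:
        idx = rng.choice(n_genes, size=s, replace=False)
        genes = sorted(universe[i] for i in idx)
        return membership, {planted.set_id: genes}, universe
    target_mean = planted.fold_enrichment * s * m / n_genes
    if target_mean > min(s, m):
        raise ValueError(
            f"fold {planted.fold_enrichment} infeasible: mean overlap "
            f"{target_mean:.1f} exceeds min(set, module) = {min(s, m)}"
        )
    overlap = _draw_overlap(n_genes, m, s, target_mean, rng)
    in_module = [g for g in universe if membership.get(g) == planted.module_id]
    outside = [g for g in universe if membership.get(g) != planted.module_id]
    picked = list(rng.choice(len(in_module), size=overlap, replace=False)) if overlap else []
    picked_out = list(rng.choice(len(outside), size=s - overlap, replace=False))
    genes = sorted(
        [in_module[i] for i in picked] + [outside[i] for i in picked_out]
    )
    return membership, {planted.set_id: genes}, universe


def _draw_overlap(
    n_genes: int, m: int, s: int, target_mean: float, rng: np.random.Generator
) -> int:
    """Fisher noncentral hypergeometric overlap with the requested mean."""
    from scipy import optimize, stats

    if target_mean == 0:
        return 0
    lo, hi = min(0, s + m - n_genes), min(s, m)
    if target_mean >= hi:
        return hi

    def mean_at(log_odds: float) -> float:
        return float(
            stats.nchypergeom_fisher.mean(n_genes, m, s, float(np.exp(log_odds)))
        )

    log_odds = optimize.brentq(
        lambda x: mean_at(x) - target_mean, -25.0, 25.0, xtol=1e-10
    )
    dist = stats.nchypergeom_fisher(n_genes, m, s, float(np.exp(log_odds)))
    return int(dist.ppf(rng.uniform()))
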