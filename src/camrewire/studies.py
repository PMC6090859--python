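"""Self-contained calibration studies: simulate with known truth, analyse, score.

Each study freezes its own conditions (sample sizes, effect sizes, noise) and
derives every replicate seed mechanically from one base seed, so a study is a
pure function of that seed.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import diel, kaks, simulate
from .enrichment import enrich, poisson_tail
from .io import RunConfig
from .pipeline import run_pipeline

__all__ = [
    "scan_recovery_study",
    "scan_null_study",
    "diel_recovery_study",
    "diel_interpolation_error",
    "enrichment_null_study",
    "enrichment_power_study",
    "clade_roundtrip_study",
    "determinism_study",
]

# frozen scan conditions: 300-codon genes, dN/dS 4 planted on codons
# [100, 150), background 0.2, pair divergence 0.3 substitutions/codon
_SCAN_LENGTH = 300
_SCAN_PLANTED = (100, 150)
_SCAN_OMEGA_IN = 4.0
_SCAN_OMEGA_OUT = 0.2
_SCAN_BRANCH = 0.3


def _scan_omega_map() -> simulate.OmegaMap:
    return simulate.OmegaMap.planted(
        _SCAN_LENGTH, *_SCAN_PLANTED, _SCAN_OMEGA_IN, _SCAN_OMEGA_OUT
    )


def scan_recovery_study(seed: int = 0, n_genes: int = 50) -> dict:
    """Fraction of planted-selection genes recovered by the sliding scan.

    A gene counts as recovered when a significant positive region overlaps at
    least half of the planted segment.
    """
    start, end = _SCAN_PLANTED
    need = (end - start) // 2
    omega_map = _scan_omega_map()
    hits = 0
    for i in range(n_genes):
        aln, _ = simulate.simulate_codon_pair(
            _SCAN_LENGTH, omega_map, _SCAN_BRANCH, seed=seed + i
        )
        regions = kaks.call_regions(kaks.sliding_profile(aln))
        for r in regions:
            if r.significant and min(r.end_codon, end) - max(r.start_codon, start) >= need:
                hits += 1
                break
    return {"recovery_rate": hits / n_genes, "n": n_genes}


def scan_null_study(seed: int = 0, n_genes: int = 200) -> dict:
    """Fraction of neutral-background genes with any significant region."""
    omega_map = simulate.OmegaMap.uniform(_SCAN_LENGTH, _SCAN_OMEGA_OUT)
    fp = 0
    for i in range(n_genes):
        aln, _ = simulate.simulate_codon_pair(
            _SCAN_LENGTH, omega_map, _SCAN_BRANCH, seed=seed + 10_000 + i
        )
        regions = kaks.call_regions(kaks.sliding_profile(aln))
        fp += any(r.significant for r in regions)
    return {"false_positive_rate": fp / n_genes, "n": n_genes}


def _diel_truth(i: int, n_pairs: int, rng: np.random.Generator) -> simulate.DielTruth:
    """Frozen study design: half the pairs carry an exact 12 h shift.

    Shifted pairs alternate the two patterns seen in CAM/C3 comparisons —
    morning-to-night (C3 peak 3 h, CAM peak 15 h) and afternoon-to-night
    (C3 peak 8 h, a sampled afternoon timepoint, CAM peak 20 h) — matching
    their roughly equal observed frequencies; unshifted pairs share one
    uniform random peak.
    """
    if i < n_pairs // 2:
        if i % 2 == 0:
            peak_b, peak_a = 3.0, 15.0
        else:
            peak_b, peak_a = 8.0, 20.0
    else:
        peak_b = peak_a = float(rng.uniform(0.0, 24.0))
    return simulate.DielTruth(f"pair{i:04d}", peak_a=peak_a, peak_b=peak_b, noise_sd=0.3)


def diel_recovery_study(seed: int = 0, n_pairs: int = 200) -> dict:
    """Shift-class accuracy of the full interpolate/Z-score/classify chain."""
    rng = np.random.default_rng(seed + 555)
    correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for i in range(n_pairs):
        truth = _diel_truth(i, n_pairs, rng)
        sa, sb = simulate.simulate_diel_pair(truth, seed=seed + i)
        za = diel.zscore(diel.interpolate_to_grid(sa))
        zb = diel.zscore(diel.interpolate_to_grid(sb))
        call = diel.classify_shift(diel.DielPair(truth.pair_id, za, zb))
        key = (truth.true_shift_class, call.shift_class)
        confusion[key] = confusion.get(key, 0) + 1
        correct += call.shift_class == truth.true_shift_class
    return {
        "accuracy": correct / n_pairs,
        "n": n_pairs,
        "confusion": {f"{t}->{p}": c for (t, p), c in sorted(confusion.items())},
    }


def diel_interpolation_error(peak: float = 15.0) -> dict:
    """Max abs error of grid interpolation on a noiseless cosine (3 h grid)."""
    t = np.asarray(diel.AGAVE_GRID)
    series = diel.DielSeries(
        "cosine", "cam", tuple(t), tuple(np.cos(2 * np.pi * (t - peak) / 24.0))
    )
    interp = diel.interpolate_to_grid(series)
    grid = np.asarray(diel.COMMON_GRID)
    truth = np.cos(2 * np.pi * (grid - peak) / 24.0)
    err = float(np.max(np.abs(np.asarray(interp.values) - truth)))
    return {"max_abs_error": err, "n": grid.size}


# enrichment designs: the power run uses a 2000-gene universe with sixteen
# 100-gene modules and a 20-gene set planted at 8-fold in module M11; the
# null-calibration run uses per-cell expected count 0.8 (20000 genes, sixteen
# 200-gene modules, 80-gene set), where the discrete level-0.05 Poisson test
# attains size 0.0475 — at integer expected counts the achievable size of a
# discrete tail test is far below nominal, which would measure the test's
# discreteness rather than its calibration
_POWER_SIZES = {f"M{k:02d}": 100 for k in range(1, 17)}
_NULL_SIZES = {f"M{k:02d}": 200 for k in range(1, 17)}


def enrichment_null_study(seed: int = 0, n_reps: int = 500) -> dict:
    """Rate of raw p < 0.05 across module cells under uniform set draws."""
    low = 0
    total = 0
    for rep in range(n_reps):
        mem, sets, uni = simulate.simulate_module_membership(
            20_000,
            _NULL_SIZES,
            simulate.PlantedEnrichment("null_set", "M11", 80, 1.0),
            seed=seed + 20_000 + rep,
        )
        results, _ = enrich(mem, sets, uni)
        for r in results:
            if r.category != "Non-module":
                low += r.p_over < 0.05
                total += 1
    return {"p05_rate": low / total, "n": total}


def enrichment_power_study(seed: int = 0, n_reps: int = 100) -> dict:
    """Fraction of replicates flagging the planted cell at q < 0.05."""
    hits = 0
    for rep in range(n_reps):
        mem, sets, uni = simulate.simulate_module_membership(
            2_000,
            _POWER_SIZES,
            simulate.PlantedEnrichment("set_2a", "M11", 20, 8.0),
            seed=seed + 30_000 + rep,
        )
        results, _ = enrich(mem, sets, uni)
        cell = next(r for r in results if r.category == "M11")
        hits += cell.q_over < 0.05
    return {"power": hits / n_reps, "n": n_reps}


def poisson_worked_cell() -> dict:
    """Upper Poisson tail for an observed count of 4 at expectation 1."""
    return {"p": poisson_tail(4, 1.0), "n": 1}


def clade_roundtrip_study(seed: int = 0) -> dict:
    """Round-trip: generated clade structure is recovered exactly."""
    roster = {
        "aam": "CAM", "ade": "CAM", "ate": "CAM",
        "ath": "C3", "osa": "C3", "ptr": "C3",
        "zma": "C4", "sbi": "C4",
        "ppa": "NVP", "cre": "NVP",
    }
    requested = {
        "NVP:C3:CAM:C4": 40,
        "NVP:C3:CAM": 10,
        "C3:CAM:C4": 30,
        "C3:CAM": 12,
        "C3:C4": 18,
        "CAM-only": 25,
        "C3-only": 8,
        "C4-only": 7,
    }
    from .clades import partition_groups

    spec = simulate.CladeSpec(roster=roster, clade_counts=requested)
    groups = simulate.simulate_ortholog_table(spec, seed=seed + 40_000)
    by_clade, fractions = partition_groups(groups, roster)
    counts = {label: len(gs) for label, gs in by_clade.items()}
    exact = counts == requested
    row_sums_ok = bool(np.allclose(fractions.sum(axis=1), 1.0, atol=1e-12))
    return {
        "roundtrip_exact": exact,
        "row_sums_ok": row_sums_ok,
        "n": sum(requested.values()),
    }


def determinism_study(seed: int, work_dir: str | Path) -> dict:
    """Byte-identity of two full pipeline runs from the same seed."""
    work_dir = Path(work_dir)
    digests = []
    for tag in ("run1", "run2"):
        cfg = RunConfig(
            seed=seed,
            out_dir=str(work_dir / tag),
            n_kaks_genes=3,
            n_diel_pairs=12,
            n_module_genes=500,
            planted_set_size=10,
        )
        manifest = run_pipeline(cfg)
        digests.append(manifest["outputs_sha256"])
    return {"identical": digests[0] == digests[1], "n": len(digests[0])}
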