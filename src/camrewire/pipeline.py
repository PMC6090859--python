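"""End-to-end pipeline driver over synthetic inputs.

Stages run in dependency order: ``simulate`` writes every input the analysis
stages read (codon-pair FASTAs with a planted positively selected segment,
two-species diel expression matrices with a truth sidecar, an ortholog table
with prescribed clade structure, module memberships with a planted enriched
set); ``kaks``, ``dielshift``, ``clades`` and ``enrich`` consume those files
and write TSV results plus a JSON manifest of parameters and output digests.
All randomness flows from the config seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diel, io, kaks, simulate
from .clades import partition_groups
from .enrichment import enrich
from .io import RunConfig

__all__ = ["run_pipeline"]

_STAGE_ORDER = ("simulate", "kaks", "dielshift", "clades", "enrich")


def _log(stage: str, msg: str) -> None:
    print(f"[camrewire:{stage}] {msg}", file=sys.stderr)


def _subseed(seed: int, k: int) -> int:
    return int((seed * 100_003 + 7919 * k) % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# stage: simulate


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    rng_dir = out / "inputs"
    rng_dir.mkdir(parents=True, exist_ok=True)

    # codon pairs with a planted high-omega segment
    omega_map = simulate.OmegaMap.planted(
        cfg.gene_length_codons,
        cfg.planted_start,
        cfg.planted_end,
        cfg.omega_in,
        cfg.omega_out,
    )
    truth_rows = []
    for i in range(cfg.n_kaks_genes):
        aln, _ = simulate.simulate_codon_pair(
            cfg.gene_length_codons,
            omega_map,
            cfg.branch_length,
            kappa=cfg.kappa,
            seed=_subseed(cfg.seed, i),
            gene_id=f"gene{i:03d}",
        )
        io.write_codon_pair_fasta(aln, rng_dir / f"gene{i:03d}.fasta")
        truth_rows.append(
            {
                "gene_id": aln.gene_id,
                "planted_start_codon0": cfg.planted_start,
                "planted_end_codon0": cfg.planted_end,
                "omega_in": cfg.omega_in,
                "omega_out": cfg.omega_out,
            }
        )
    _write_tsv(pd.DataFrame(truth_rows), rng_dir / "kaks_truth.tsv")

    # diel ortholog pairs: half shifted (alternating morning-to-night and
    # afternoon-to-night), half unshifted with a shared random peak
    n = cfg.n_diel_pairs
    rng = np.random.default_rng(_subseed(cfg.seed, 1001))
    rows_a, rows_b, truth_rows, rbh_rows, group_lines = [], [], [], [], []
    for i in range(n):
        if i < n // 2:
            if i % 2 == 0:
                peak_b, peak_a = 3.0, 15.0  # morning -> early night
            else:
                peak_b, peak_a = 8.0, 20.0  # afternoon -> late night
        else:
            peak_b = peak_a = float(rng.uniform(0, 24))
        truth = simulate.DielTruth(
            f"pair{i:03d}", peak_a=peak_a, peak_b=peak_b, noise_sd=cfg.diel_noise_sd
        )
        sa, sb = simulate.simulate_diel_pair(truth, seed=_subseed(cfg.seed, 2000 + i))
        # RPKM-like positive scale; classification is scale/offset invariant
        rows_a.append([f"aam{i:03d}"] + [10 + 5 * v for v in sa.values])
        rows_b.append([f"ath{i:03d}"] + [10 + 5 * v for v in sb.values])
        truth_rows.append(
            {
                "pair_id": truth.pair_id,
                "gene_a": f"aam{i:03d}",
                "gene_b": f"ath{i:03d}",
                "peak_a_h": truth.peak_a,
                "peak_b_h": truth.peak_b,
                "true_shift_class": truth.true_shift_class,
            }
        )
        rbh_rows.append({"gene_a": f"aam{i:03d}", "gene_b": f"ath{i:03d}"})
        group_lines.append(f"DG{i:05d}: aam|aam{i:03d} ath|ath{i:03d}")
    mat_a = pd.DataFrame(
        [r[1:] for r in rows_a], index=[r[0] for r in rows_a], columns=diel.AGAVE_GRID
    )
    mat_b = pd.DataFrame(
        [r[1:] for r in rows_b],
        index=[r[0] for r in rows_b],
        columns=diel.ARABIDOPSIS_GRID,
    )
    io.write_expression_matrix(mat_a, rng_dir / "expression_cam.tsv")
    io.write_expression_matrix(mat_b, rng_dir / "expression_c3.tsv")
    _write_tsv(pd.DataFrame(truth_rows), rng_dir / "diel_truth.tsv")
    _write_tsv(pd.DataFrame(rbh_rows), rng_dir / "rbh_pairs.tsv")
    (rng_dir / "diel_groups.txt").write_text("\n".join(group_lines) + "\n")

    # ortholog table with prescribed clade structure
    roster = {
        "aam": "CAM", "ade": "CAM", "ate": "CAM",
        "ath": "C3", "osa": "C3", "ptr": "C3",
        "zma": "C4", "sbi": "C4",
        "ppa": "NVP", "cre": "NVP",
    }
    spec = simulate.CladeSpec(
        roster=roster,
        clade_counts={
            "NVP:C3:CAM:C4": 30,
            "C3:CAM:C4": 25,
            "C3:CAM": 10,
            "CAM-only": 15,
            "C3:C4": 10,
            "C3-only": 5,
            "C4-only": 5,
        },
    )
    groups = simulate.simulate_ortholog_table(spec, seed=_subseed(cfg.seed, 3001))
    io.write_groups(groups, rng_dir / "ortholog_groups.txt")
    types_df = pd.DataFrame(
        sorted(roster.items()), columns=["species", "photosynthesis_type"]
    )
    _write_tsv(types_df, rng_dir / "species_types.tsv")
    _write_tsv(
        pd.DataFrame(sorted(spec.clade_counts.items()), columns=["clade", "n_groups"]),
        rng_dir / "clade_truth.tsv",
    )

    # module membership with one planted enriched set
    module_sizes = {f"M{k:02d}": max(1, cfg.n_module_genes // 20) for k in range(1, 17)}
    planted = simulate.PlantedEnrichment(
        "set_2a", "M11", cfg.planted_set_size, cfg.planted_fold
    )
    membership, gene_sets, universe = simulate.simulate_module_membership(
        cfg.n_module_genes, module_sizes, planted, seed=_subseed(cfg.seed, 4001)
    )
    _write_tsv(
        pd.DataFrame(
            [(g, membership.get(g, "Non-module")) for g in universe],
            columns=["gene_id", "module"],
        ),
        rng_dir / "module_membership.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [(s, g) for s, genes in gene_sets.items() for g in genes],
            columns=["gene_set", "gene_id"],
        ),
        rng_dir / "gene_sets.tsv",
    )
    _log("simulate", f"wrote inputs for {cfg.n_kaks_genes} genes, {n} diel pairs")


# ---------------------------------------------------------------------------
# analysis stages


def _stage_kaks(cfg: RunConfig, out: Path) -> None:
    in_dir = out / "inputs"
    fastas = sorted(in_dir.glob("gene*.fasta"))
    if not fastas:
        raise FileNotFoundError("kaks stage: no simulated codon pairs (run simulate)")
    profiles, regions = [], []
    for fa in fastas:
        aln = io.read_codon_pair_fasta(fa)
        prof = kaks.sliding_profile(aln, window=cfg.window, step=cfg.step)
        profiles.append(prof)
        regions.extend(
            kaks.call_regions(
                prof, comparison="spA-spB", min_run=cfg.min_run, alpha=cfg.alpha
            )
        )
    _write_tsv(io.profile_table(profiles), out / "kaks_profiles.tsv")
    _write_tsv(io.region_table(regions), out / "kaks_regions.tsv")
    _log("kaks", f"{len(profiles)} profiles, {len(regions)} candidate regions")


def _stage_dielshift(cfg: RunConfig, out: Path) -> None:
    in_dir = out / "inputs"
    mat_a = io.read_expression_matrix(in_dir / "expression_cam.tsv")
    mat_b = io.read_expression_matrix(in_dir / "expression_c3.tsv")
    rbh = io.read_rbh_pairs(in_dir / "rbh_pairs.tsv")
    groups = io.read_groups(in_dir / "diel_groups.txt")
    mat_a = diel.filter_expressed(mat_a, min_samples=4, min_mean=5.0)
    mat_b = diel.filter_expressed(mat_b, min_samples=4, min_mean=5.0)
    pairs_kept, _report = diel.pair_orthologs(rbh, groups)
    pairs, calls, zrows = [], [], []
    for ga, gb in pairs_kept:
        if ga not in mat_a.index or gb not in mat_b.index:
            continue
        sa = io.series_from_matrix(mat_a, ga, "cam")
        sb = io.series_from_matrix(mat_b, gb, "c3")
        za = diel.zscore(diel.interpolate_to_grid(sa))
        zb = diel.zscore(diel.interpolate_to_grid(sb))
        pair = diel.DielPair(f"{ga}|{gb}", za, zb)
        pairs.append(pair)
        calls.append(diel.classify_shift(pair))
        zrows.append([pair.pair_id, "cam"] + list(za.values))
        zrows.append([pair.pair_id, "c3"] + list(zb.values))
    labels, _ = diel.cluster_pairs(pairs, k=2) if len(pairs) > 1 else (np.ones(len(pairs), int), None)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "pair_id": c.pair_id,
                    "peak_cam_h": c.peak_a,
                    "peak_c3_h": c.peak_b,
                    "bin_cam": c.bin_a,
                    "bin_c3": c.bin_b,
                    "shift_class": c.shift_class,
                    "cluster": int(l),
                }
                for c, l in zip(calls, labels)
            ]
        ),
        out / "diel_shift_calls.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            zrows, columns=["pair_id", "species"] + [f"{t:g}h" for t in diel.COMMON_GRID]
        ),
        out / "diel_zprofiles.tsv",
    )
    _log("dielshift", f"{len(calls)} ortholog pairs classified")


def _stage_clades(cfg: RunConfig, out: Path) -> None:
    in_dir = out / "inputs"
    groups = io.read_groups(in_dir / "ortholog_groups.txt")
    types = io.read_species_types(in_dir / "species_types.tsv")
    by_clade, fractions = partition_groups(groups, types)
    _write_tsv(
        pd.DataFrame(
            [(label, g.group_id) for label in sorted(by_clade) for g in by_clade[label]],
            columns=["clade", "group_id"],
        ),
        out / "clade_assignments.tsv",
    )
    fractions.to_csv(out / "clade_fractions.tsv", sep="\t", float_format="%.10g")
    _log("clades", f"{len(groups)} groups in {len(by_clade)} clades")


def _stage_enrich(cfg: RunConfig, out: Path) -> None:
    in_dir = out / "inputs"
    membership_df = pd.read_csv(in_dir / "module_membership.tsv", sep="\t")
    sets_df = pd.read_csv(in_dir / "gene_sets.tsv", sep="\t")
    universe = list(membership_df["gene_id"])
    membership = {
        r.gene_id: r.module
        for r in membership_df.itertuples()
        if r.module != "Non-module"
    }
    gene_sets: dict[str, list[str]] = {}
    for r in sets_df.itertuples():
        gene_sets.setdefault(r.gene_set, []).append(r.gene_id)
    results, _report = enrich(
        membership, gene_sets, universe, alpha_levels=cfg.alpha_levels
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_set": r.gene_set,
                    "category": r.category,
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_over": r.p_over,
                    "p_under": r.p_under,
                    "q_over": r.q_over,
                    "direction": r.direction,
                    "flag": r.flag,
                }
                for r in results
            ]
        ),
        out / "enrichment.tsv",
    )
    _log("enrich", f"{len(results)} set x category cells")


_STAGES = {
    "simulate": _stage_simulate,
    "kaks": _stage_kaks,
    "dielshift": _stage_dielshift,
    "clades": _stage_clades,
    "enrich": _stage_enrich,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages and write a manifest; returns the manifest."""
    unknown = set(cfg.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in _STAGE_ORDER:
        if stage in cfg.stages:
            _STAGES[stage](cfg, out)
    digests = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digests[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "outputs_sha256": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
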