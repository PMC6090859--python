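"""File formats: FASTA codon pairs, OrthoMCL groups text, TSV tables, config.

All tables are plain TSV with headers naming units; codon coordinates in
outputs are 0-based half-open (a 1-based codon column is added to region
reports for cross-referencing against protein numbering).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clades import OrthologGroup
from .diel import DielSeries
from .kaks import CodonAlignment, KaKsProfile, PositiveRegion

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_codon_pair_fasta",
    "write_codon_pair_fasta",
    "read_groups",
    "write_groups",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_species_types",
    "read_rbh_pairs",
    "read_presence_matrix",
    "profile_table",
    "region_table",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file, preserving record order; duplicate ids are errors."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_codon_pair_fasta(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read a two-record FASTA as one pairwise codon alignment.

    Record ids are taken as ``species`` or ``species|gene``; gap characters
    are allowed and must be stripped by the caller (``kaks.strip_gaps``) —
    this reader only checks the record count.
    """
    records = read_fasta(path)
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, got {len(records)}")
    a, b = records
    sp_a, sp_b = a.id.split("|")[0], b.id.split("|")[0]
    gid = gene_id or Path(path).stem
    from .kaks import strip_gaps

    return strip_gaps(gid, sp_a, sp_b, str(a.seq), str(b.seq))


def write_codon_pair_fasta(aln: CodonAlignment, path: str | Path) -> None:
    write_fasta(
        [
            SeqRecord(Seq(aln.seq_a), id=f"{aln.species_a}|{aln.gene_id}", description=""),
            SeqRecord(Seq(aln.seq_b), id=f"{aln.species_b}|{aln.gene_id}", description=""),
        ],
        path,
    )


# ---------------------------------------------------------------------------
# OrthoMCL groups dialect: "GROUP_ID: sp|gene sp|gene ..."


def read_groups(path: str | Path) -> list[OrthologGroup]:
    groups: list[OrthologGroup] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing 'GROUP_ID:' prefix")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate group id {gid!r}")
            seen.add(gid)
            members: dict[str, list[str]] = {}
            for token in rest.split():
                if "|" not in token:
                    raise ValueError(
                        f"{path}:{lineno}: member {token!r} lacks 'species|gene' form"
                    )
                sp, _, gene = token.partition("|")
                members.setdefault(sp, []).append(gene)
            groups.append(
                OrthologGroup(gid, {sp: tuple(gs) for sp, gs in members.items()})
            )
    return groups


def write_groups(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            tokens = [
                f"{sp}|{gene}" for sp in sorted(g.members) for gene in g.members[sp]
            ]
            fh.write(f"{g.group_id}: {' '.join(tokens)}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x timepoint matrix; column headers are hours after lights-on."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.columns = [f"{float(c):g}" for c in out.columns]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def series_from_matrix(df: pd.DataFrame, gene_id: str, species: str) -> DielSeries:
    row = df.loc[gene_id]
    return DielSeries(
        gene_id,
        species,
        tuple(float(t) for t in df.columns),
        tuple(float(v) for v in row.to_numpy()),
    )


def read_species_types(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_rbh_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.iloc[:, :2].astype(str).to_numpy()]


def read_presence_matrix(path: str | Path, evalue_cutoff: float = 1e-5) -> pd.DataFrame:
    """Long-format (gene, species, present-or-E-value) TSV -> boolean matrix.

    The third column may be boolean-ish (0/1, true/false) or a BLASTp
    E-value, thresholded at ``evalue_cutoff``.
    """
    df = pd.read_csv(path, sep="\t")
    gene, sp, val = df.columns[:3]
    raw = df[val]
    lowered = raw.astype(str).str.lower()
    if set(lowered.unique()) <= {"true", "false", "0", "1"}:
        present = lowered.isin({"true", "1"})
    else:
        present = pd.to_numeric(raw) <= evalue_cutoff
    wide = (
        df.assign(_present=present.astype(int))
        .pivot_table(index=gene, columns=sp, values="_present", aggfunc="max")
        .fillna(0)
        .astype(bool)
    )
    wide.index.name = "gene_id"
    return wide


def profile_table(profiles: Iterable[KaKsProfile]) -> pd.DataFrame:
    """Long-format per-window table (window_start is a 0-based codon index)."""
    rows = []
    for prof in profiles:
        for start, est in prof.windows:
            rows.append(
                {
                    "gene_id": prof.gene_id,
                    "window_start_codon0": start,
                    "window_size": prof.window,
                    "Ka": est.ka,
                    "Ks": est.ks,
                    "ratio": est.ratio,
                    "saturated": est.saturated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "window_start_codon0",
            "window_size",
            "Ka",
            "Ks",
            "ratio",
            "saturated",
        ],
    )


def region_table(regions: Iterable[PositiveRegion]) -> pd.DataFrame:
    """Region report; adds 1-based inclusive codon columns for protein numbering."""
    rows = []
    for r in regions:
        rows.append(
            {
                "gene_id": r.gene_id,
                "comparison": r.comparison,
                "start_codon0": r.start_codon,
                "end_codon0": r.end_codon,
                "start_codon1": r.start_codon + 1,
                "end_codon1": r.end_codon,
                "n_windows": r.n_windows,
                "mean_ratio": r.mean_ratio,
                "p_value": r.p_value,
                "significant": r.significant,
                "degenerate_variance": r.degenerate_variance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "comparison",
            "start_codon0",
            "end_codon0",
            "start_codon1",
            "end_codon1",
            "n_windows",
            "mean_ratio",
            "p_value",
            "significant",
            "degenerate_variance",
        ],
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Parameters for the pipeline driver; round-trips losslessly via YAML."""

    seed: int = 0
    out_dir: str = "camrewire_out"
    stages: tuple[str, ...] = ("simulate", "kaks", "dielshift", "clades", "enrich")
    # kaks scan
    window: int = 50
    step: int = 1
    min_run: int = 25
    alpha: float = 0.05
    # simulation sizes
    n_kaks_genes: int = 10
    gene_length_codons: int = 300
    planted_start: int = 100
    planted_end: int = 150
    omega_in: float = 4.0
    omega_out: float = 0.2
    branch_length: float = 0.3
    kappa: float = 2.0
    n_diel_pairs: int = 40
    diel_noise_sd: float = 0.3
    # clades / enrichment
    evalue_cutoff: float = 1e-5
    fdr_family: str = "per-set"
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    n_module_genes: int = 2000
    planted_fold: float = 8.0
    planted_set_size: int = 20

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        data["alpha_levels"] = list(self.alpha_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "alpha_levels" in data:
            data["alpha_levels"] = tuple(data["alpha_levels"])
        return cls(**data)
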