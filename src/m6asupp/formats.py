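"""Shared format readers/writers, pipeline configuration and run manifests.

Dialects are strict and fixed: BED is 0-based half-open; GTF is written
1-based closed; FASTA is wrapped at 60 columns (lowercase accepted on read,
uppercased internally); TSV has a header, UTF-8 encoding, and '.' for
missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .annotation import TranscriptModel
from .ejc_model import EJCModelParams
from .simulate import GeneratorConfig

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ----------------------------------------------------------------------
# TSV
# ----------------------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], encoding="utf-8")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", encoding="utf-8")


# ----------------------------------------------------------------------
# BED
# ----------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 (0-based half-open), returned with BED6 column names."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise BedParseError(f"{path}:{lineno}: bad interval [{start},{end})")
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else ".",
                "score": parts[4] if len(parts) > 4 else 0,
                "strand": parts[5] if len(parts) > 5 else ".",
            })
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False, encoding="utf-8")


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> dict of id -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable, path) -> None:
    """Write sequences (dict or SeqRecord iterable) wrapped at 60 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(seqs, Mapping):
        records = [SeqRecord(Seq(s), id=name, description="")
                   for name, s in seqs.items()]
    else:
        records = list(seqs)
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


# ----------------------------------------------------------------------
# GTF writing (reading lives in annotation.load_gtf)
# ----------------------------------------------------------------------

def write_gtf(models: Mapping[str, TranscriptModel], path) -> None:
    """Write exon and CDS features, 1-based closed coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(models):
            t = models[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in sorted(t.exons):
                fh.write(f"{t.chrom}\tm6asupp\texon\t{s + 1}\t{e}\t.\t"
                         f"{t.strand}\t.\t{attrs}\n")
            if t.is_coding:
                for s, e in t.transcript_interval_to_genomic(t.cds_start, t.cds_end):
                    fh.write(f"{t.chrom}\tm6asupp\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t0\t{attrs}\n")


# ----------------------------------------------------------------------
# Pipeline configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and model settings shared by the CLI subcommands."""

    seed: int = 0
    alpha: float = 0.05                 # reporter call FDR threshold
    fdr_thresh: float = 0.1             # region-call FDR threshold
    lfc_thresh: float = 1.0             # region-call |log2FC| threshold
    coloc_window: int = 100             # nt window for colocalization
    n_bins: int = 100                   # bins for binned correlations
    test: str = "ttest"                 # reporter test: ttest | wilcoxon
    region_test: str = "cmh"            # region test: cmh | fisher
    kernel: str = "logistic"            # protection kernel
    ejc_params: EJCModelParams | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.fdr_thresh < 1:
            raise ConfigError("alpha and fdr_thresh must be in (0,1)")
        if self.lfc_thresh < 0 or self.coloc_window < 0 or self.n_bins < 1:
            raise ConfigError("lfc_thresh/coloc_window/n_bins out of domain")
        if self.test not in ("ttest", "wilcoxon"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.region_test not in ("cmh", "fisher"):
            raise ConfigError(f"unknown region_test {self.region_test!r}")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "generator" in raw:
        gknown = {f.name for f in dataclasses.fields(GeneratorConfig)}
        gunknown = set(raw["generator"]) - gknown
        if gunknown:
            raise ConfigError(
                f"{path}: unknown generator keys {sorted(gunknown)}")
        graw = dict(raw["generator"])
        if graw.get("ejc_params") is not None:
            graw["ejc_params"] = EJCModelParams(**graw["ejc_params"])
        if "exons_per_gene" in graw:
            graw["exons_per_gene"] = tuple(graw["exons_per_gene"])
        raw["generator"] = GeneratorConfig(**graw)
    if raw.get("ejc_params") is not None:
        raw["ejc_params"] = EJCModelParams(**raw["ejc_params"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------------
# Run manifest
# ----------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, subcommand: str, config: PipelineConfig,
                   inputs: Iterable[str] = (), outputs: Iterable[str] = (),
                   extra: dict | None = None) -> Path:
    """Record everything needed to reproduce a run: subcommand, config,
    seed, and input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(config)
    manifest = {
        "subcommand": subcommand,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "config": cfg,
        "inputs": {str(p): file_checksum(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest["extra"] = extra
    path = out_dir / f"manifest_{subcommand}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return path
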