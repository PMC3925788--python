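"""Readers and writers for the package's on-disk formats.

FASTA goes through Biopython; GFF3, link/depth/pileup TSVs and the truth
JSON are simple tabular formats handled with pandas / the json module.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CircularGenome, GeneAnnotation, RepeatPair, TruthSet


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path, records: dict[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_genome(path, genome_id: str | None = None, circular: bool = True) -> CircularGenome:
    records = read_fasta(path)
    if genome_id is None:
        if len(records) != 1:
            raise ValueError(f"{path}: expected a single sequence, found {len(records)}")
        genome_id, seq = next(iter(records.items()))
    else:
        seq = records[genome_id]
    return CircularGenome(id=genome_id, sequence=seq, is_circular=circular)


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def write_gff3(path, seq_id: str, genes: list[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                seq_id, "mitomosaic", g.type, str(g.start), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")


def read_gff3(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(GeneAnnotation(
                gene_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                start=int(f[3]), end=int(f[4]), strand=f[6], type=f[2],
            ))
    return genes


# ---------------------------------------------------------------------------
# links / depths / pileups
# ---------------------------------------------------------------------------

LINK_COLUMNS = ["contig_a", "end_a", "contig_b", "end_b", "support"]


def write_links(path, links: list[tuple[str, str, str, str, int]]) -> None:
    pd.DataFrame(links, columns=LINK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_links(path) -> list[tuple[str, str, str, str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"support": int})
    return [tuple(r) for r in df[LINK_COLUMNS].itertuples(index=False)]


def write_depths(path, depths: dict[str, float]) -> None:
    pd.DataFrame(sorted(depths.items()), columns=["contig_id", "mean_depth"]) \
        .to_csv(path, sep="\t", index=False)


def read_depths(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["contig_id"], df["mean_depth"].astype(float)))


def write_pileup(path, pileup: pd.DataFrame) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# truth JSON
# ---------------------------------------------------------------------------

def write_truth(path, truth: TruthSet) -> None:
    payload = {
        "planted_repeats": [
            {"start1": r.start1, "start2": r.start2, "length": r.length,
             "orientation": r.orientation, "mismatches": r.mismatches}
            for r in truth.planted_repeats
        ],
        "planted_junctions": [
            {"subject_positions": list(pos), "footprint_length": fl}
            for pos, fl in truth.planted_junctions
        ],
        "planted_editing": [
            {**site, "samples": sorted(site["samples"])}
            for site in truth.planted_editing
        ],
        "contig_origins": {
            cid: {"interval": list(interval), "class": cls}
            for cid, (interval, cls) in truth.contig_origins.items()
        },
        "genes": [
            {"gene_id": g.gene_id, "start": g.start, "end": g.end,
             "strand": g.strand, "type": g.type}
            for g in truth.genes
        ],
        "planted_fusion": truth.planted_fusion,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    truth = TruthSet()
    truth.planted_repeats = [RepeatPair(**r) for r in payload["planted_repeats"]]
    truth.planted_junctions = [
        (tuple(j["subject_positions"]), j["footprint_length"])
        for j in payload["planted_junctions"]
    ]
    truth.planted_editing = [
        {**site, "samples": set(site["samples"])} for site in payload["planted_editing"]
    ]
    truth.contig_origins = {
        cid: (tuple(v["interval"]), v["class"])
        for cid, v in payload["contig_origins"].items()
    }
    truth.genes = [GeneAnnotation(**g) for g in payload["genes"]]
    truth.planted_fusion = payload.get("planted_fusion")
    return truth


# ---------------------------------------------------------------------------
# bundled data
# ---------------------------------------------------------------------------

def published_alignment_path() -> Path:
    """Path to the bundled BLAST table of published RRIM 600 mitochondrial
    contigs against the BPM 24 master circle (the 11 rearranged contigs)."""
    return Path(__file__).parent / "data" / "rrim600_vs_bpm24_master_circle.tsv"
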