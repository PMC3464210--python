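"""File-format helpers: FASTA/FASTQ/SAM/BED/TSV/JSON round-trips.

Small or structured records go through the established libraries
(Biopython for FASTA, pysam for SAM, pandas for tables); bulk FASTQ is
written with plain buffered text for throughput.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import AdjacencyObservation
from .catalog import ArrangementStates, SignedPermutation
from .matepair import BreakpointCall, LibrarySpec, ReadHit, UNIQUE


# -- FASTA ------------------------------------------------------------------

def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- FASTQ ------------------------------------------------------------------

def write_fastq_pairs(
    prefix: str | Path, pairs: Sequence[tuple[str, str, str]]
) -> tuple[Path, Path]:
    """Write mate pairs to <prefix>_1.fq / <prefix>_2.fq with /1 /2 ids."""
    p1, p2 = Path(f"{prefix}_1.fq"), Path(f"{prefix}_2.fq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pid, r1, r2 in pairs:
            q1, q2 = "I" * len(r1), "I" * len(r2)
            f1.write(f"@{pid}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@{pid}/2\n{r2}\n+\n{q2}\n")
    return p1, p2


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str]]:
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        pid = r1.id.rsplit("/", 1)[0]
        out.append((pid, str(r1.seq), str(r2.seq)))
    return out


# -- SAM --------------------------------------------------------------------

def write_sam(
    path: str | Path,
    hits: Iterable[tuple[ReadHit, str]],
    reference_name: str,
    reference_length: int,
) -> None:
    """Minimal single-reference SAM for mapped/unmapped read hits."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hit, seq in hits:
            a = pysam.AlignedSegment(out.header)
            a.query_name = hit.read_id
            a.query_sequence = seq
            if hit.status == UNIQUE:
                a.reference_id = 0
                a.reference_start = hit.position
                a.cigarstring = f"{len(seq)}M"
                a.flag = 16 if hit.strand == "-" else 0
                a.mapping_quality = 60
            else:
                a.flag = 4
                a.mapping_quality = 0
            out.write(a)


# -- karyotype matrices -----------------------------------------------------

def write_karyotypes_tsv(path: str | Path, states: Mapping[str, ArrangementStates]) -> None:
    rows = {sp: st.states for sp, st in states.items()}
    pd.DataFrame.from_dict(rows, orient="index").rename_axis("species").to_csv(
        path, sep="\t"
    )


def read_karyotypes_tsv(path: str | Path) -> dict[str, ArrangementStates]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {
        str(sp): ArrangementStates(str(sp), {c: str(df.loc[sp, c]) for c in df.columns})
        for sp in df.index
    }


# -- permutations -----------------------------------------------------------

def write_permutations_json(
    path: str | Path, perms: Mapping[str, Mapping[str, SignedPermutation]]
) -> None:
    payload = {
        sp: {arm: list(p.elements) for arm, p in arms.items()}
        for sp, arms in perms.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_permutations_json(path: str | Path) -> dict[str, dict[str, SignedPermutation]]:
    payload = json.loads(Path(path).read_text())
    return {
        sp: {arm: SignedPermutation(arm, tuple(e)) for arm, e in arms.items()}
        for sp, arms in payload.items()
    }


# -- breakpoint calls -------------------------------------------------------

def write_calls_bed(path: str | Path, calls: Sequence[BreakpointCall],
                    chrom: str = "ref") -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(f"{chrom}\t{c.start}\t{c.end}\tcall{i}:{c.strand_pair}\t{c.support}\t.\n")


def write_calls_tsv(path: str | Path, calls: Sequence[BreakpointCall]) -> None:
    from .matepair import calls_to_frame

    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# -- adjacency / ortholog tables -------------------------------------------

def read_adjacencies_tsv(path: str | Path) -> list[AdjacencyObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(AdjacencyObservation(
            species=str(row.species),
            gene_a=str(row.gene_a),
            gene_b=str(row.gene_b),
            same_scaffold=bool(getattr(row, "same_scaffold", True)),
            intergenic_distance=(
                int(row.intergenic_distance)
                if "intergenic_distance" in df.columns
                and pd.notna(row.intergenic_distance) else None
            ),
        ))
    return out


def read_orthologs_tsv(path: str | Path) -> dict[str, str]:
    """Two-column table mapping foreign gene ids to catalog anchor ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["foreign", "anchor"],
                     comment="#")
    return dict(zip(df.foreign.astype(str), df.anchor.astype(str)))


# -- library specs ----------------------------------------------------------

def read_libraries_yaml(path: str | Path) -> tuple[LibrarySpec, ...]:
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    return tuple(
        LibrarySpec(
            name=str(d["name"]),
            insert_size=int(d["insert_size"]),
            insert_sd=float(d.get("insert_sd", 0.1 * int(d["insert_size"]))),
            read_length=int(d.get("read_length", 36)),
        )
        for d in payload["libraries"]
    )
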