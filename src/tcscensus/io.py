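"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: HMMER3 per-domain tabular output (``domtblout``) or a
simple headered TSV dialect for domain hits, protein FASTA, GFF3 gene
features, and TMHMM-style transmembrane-segment tables.  All tabular
outputs are plain TSV and round-trip through the corresponding readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SearchIO, SeqIO

from .model import DomainHit, GeneFeature, ModelError, ProteinRecord, TCSCall

log = logging.getLogger(__name__)

TSV_HIT_COLUMNS = (
    "protein_id",
    "domain_name",
    "accession",
    "start",
    "end",
    "score",
    "evalue",
)


class ParseError(ValueError):
    """A malformed input line; the message names the offending line."""


# -- domain hits -----------------------------------------------------------


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Read domain hits from HMMER3 domtblout or the headered TSV dialect.

    The format is sniffed from the first non-blank line: a tab-separated
    header starting with ``protein_id`` selects the TSV dialect, anything
    else is parsed as hmmscan-style domtblout (envelope coordinates are
    used, converted to 1-based inclusive).  An empty file yields an empty
    list.
    """
    path = Path(path)
    first = _first_content_line(path)
    if first is None:
        return []
    if first.split("\t")[0].strip() == "protein_id":
        return _read_hits_tsv(path)
    return _read_hmmer_domtblout(path)


def _first_content_line(path: Path) -> Optional[str]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.rstrip("\n")
    return None


def _read_hits_tsv(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in TSV_HIT_COLUMNS if c not in header]
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: TSV header missing columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            hits.append(_hit_from_fields(row, f"{path}:{lineno}"))
    return hits


def _hit_from_fields(row: dict[str, str], where: str) -> DomainHit:
    try:
        return DomainHit(
            protein_id=row["protein_id"].strip(),
            domain_name=row["domain_name"].strip(),
            domain_accession=row.get("accession", "").strip(),
            start=int(row["start"]),
            end=int(row["end"]),
            score=float(row["score"]),
            evalue=float(row["evalue"]),
        )
    except (KeyError, ValueError, ModelError) as exc:
        raise ParseError(f"{where}: bad hit row ({exc})") from exc


def _read_hmmer_domtblout(path: Path) -> list[DomainHit]:
    """Parse hmmscan-style domtblout via Biopython's SearchIO."""
    hits: list[DomainHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult:
                for hsp in hit.hsps:
                    hits.append(
                        DomainHit(
                            protein_id=qresult.id,
                            domain_name=hit.id,
                            domain_accession=hit.accession or "",
                            # SearchIO envelope coords are 0-based half-open
                            start=hsp.env_start + 1,
                            end=hsp.env_end,
                            score=float(hsp.bitscore),
                            evalue=float(hsp.evalue),
                        )
                    )
    except (ValueError, IndexError, ModelError) as exc:
        raise ParseError(f"{path}: malformed domtblout ({exc})") from exc
    return hits


def write_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (h.protein_id, h.domain_name, h.domain_accession, h.start, h.end, h.score, h.evalue)
            for h in hits
        ],
        columns=list(TSV_HIT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path, genome_id: str = "") -> list[ProteinRecord]:
    """Read protein sequences.

    A ``genome=XYZ`` token in the FASTA description overrides the
    ``genome_id`` argument for that record (this is how the synthetic
    generator tags multi-genome FASTA files).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = genome_id
        for token in rec.description.split():
            if token.startswith("genome="):
                gid = token[len("genome="):]
        seq = str(rec.seq)
        records.append(
            ProteinRecord(protein_id=rec.id, genome_id=gid, length=len(seq), sequence=seq)
        )
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            if p.sequence is None:
                raise ValueError(f"protein {p.protein_id!r} has no sequence")
            desc = f" genome={p.genome_id}" if p.genome_id else ""
            fh.write(f">{p.protein_id}{desc}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# -- GFF3 ------------------------------------------------------------------


def read_gff(
    path: str | Path,
    genome_id: str = "",
    id_attribute: str = "ID",
    feature_types: tuple[str, ...] = ("CDS", "gene"),
) -> list[GeneFeature]:
    """Read protein-coding gene features from GFF3.

    Only features carrying the protein-identifier attribute are kept;
    features without it are skipped with a warning.  A ``genome_id``
    attribute on the feature overrides the argument.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    seen_types = {f.featuretype for f in db.all_features()}
    wanted = [t for t in feature_types if t in seen_types]
    features: list[GeneFeature] = []
    for feat in db.all_features():
        if wanted and feat.featuretype not in wanted:
            continue
        attrs = dict(feat.attributes)
        if id_attribute not in attrs:
            log.warning(
                "GFF feature at %s:%d-%d lacks %r attribute; skipped",
                feat.seqid, feat.start, feat.end, id_attribute,
            )
            continue
        gid = attrs.get("genome_id", [genome_id])[0]
        strand = "+" if feat.strand == "+" else "-"
        features.append(
            GeneFeature(
                genome_id=gid,
                contig=feat.seqid,
                protein_id=attrs[id_attribute][0],
                start=feat.start,
                end=feat.end,
                strand=strand,
            )
        )
    return features


def write_gff(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.protein_id};genome_id={f.genome_id}"
            fh.write(
                f"{f.contig}\ttcscensus\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


# -- TM tables -------------------------------------------------------------


def read_tm_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """TMHMM-like TSV: protein_id, tm_start, tm_end (one row per helix)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "tm_start", "tm_end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TM table needs columns {sorted(required)}")
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append((int(row.tm_start), int(row.tm_end)))
    return {k: sorted(v) for k, v in out.items()}


def write_tm_table(segments: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    rows = [
        (pid, s, e) for pid, segs in sorted(segments.items()) for s, e in segs
    ]
    pd.DataFrame(rows, columns=["protein_id", "tm_start", "tm_end"]).to_csv(
        path, sep="\t", index=False
    )


# -- calls and census tables ----------------------------------------------


def write_calls(calls: Iterable[TCSCall], path: str | Path) -> None:
    rows = [
        (
            c.protein_id,
            c.category,
            c.rr_subclass,
            ",".join(sorted(c.flags)),
            c.architecture_string,
        )
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["protein_id", "category", "rr_subclass", "flags", "architecture_string"],
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[TCSCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for row in df.itertuples(index=False):
        flags = set(f for f in row.flags.split(",") if f)
        calls.append(
            TCSCall(
                protein_id=row.protein_id,
                category=row.category,
                rr_subclass=row.rr_subclass or "n/a",
                flags=flags,
                architecture_string=row.architecture_string,
            )
        )
    return calls


def write_census(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    # percent columns may be float-NaN for taxa without response regulators
    return df


def tables_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Equality on the data model: NaN == NaN, dtypes reconciled."""
    if list(a.columns) != list(b.columns):
        return False
    try:
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
        )
    except AssertionError:
        return False
    return True
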