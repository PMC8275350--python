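"""FASTA input and unitig FASTA / GFA1 / GFA2 output.

Output is fully deterministic: unitig ids are assigned in sorted order of
canonical spelling, records are written in id order, and no timestamps or
environment details are embedded, so repeated runs on identical input are
byte-identical.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .extract import TilingStep, UnitigRecord


@dataclass(frozen=True)
class SeqRecord:
    """One FASTA record: identifier, free-text description, raw sequence."""

    id: str
    description: str
    sequence: str


class FastaParseError(ValueError):
    """Input could not be parsed as FASTA."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(paths: Iterable[str | Path]) -> Iterator[SeqRecord]:
    """Stream records from one or more (optionally gzipped) FASTA files.

    Records come in file order; duplicate ids are disambiguated with a
    numeric suffix and a warning. CRLF endings and line-wrapped sequences
    are normalised by the parser.
    """
    seen: dict[str, int] = {}
    for path in paths:
        with _open_text(path) as fh:
            first = fh.read(1)
            if first == "":
                continue
            if first != ">":
                raise FastaParseError(f"{path}: does not start with '>' (line 1)")
            fh.seek(0)
            for rec in SeqIO.parse(fh, "fasta"):
                rid = rec.id
                if rid in seen:
                    seen[rid] += 1
                    new_id = f"{rid}.{seen[rid]}"
                    warnings.warn(f"duplicate FASTA id {rid!r} renamed to {new_id!r}")
                    rid = new_id
                else:
                    seen[rid] = 0
                yield SeqRecord(id=rid, description=rec.description, sequence=str(rec.seq))


def unitig_name(uid: int) -> str:
    return f"cf_{uid}"


def write_unitigs_fasta(unitigs: Iterable[UnitigRecord], path: str | Path) -> None:
    """One record per unitig, ``>cf_<id> LN:i:<length>``, in id order."""
    with open(path, "wt") as fh:
        for rec in sorted(unitigs, key=lambda r: r.id):
            fh.write(f">{unitig_name(rec.id)} LN:i:{rec.length}\n{rec.spelling}\n")


def read_unitigs_fasta(path: str | Path) -> list[str]:
    """Spellings from a unitig FASTA written by :func:`write_unitigs_fasta`."""
    with _open_text(path) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]


def _flip(orientation: str) -> str:
    return "-" if orientation == "+" else "+"


def _link_key(a: str, oa: str, b: str, ob: str) -> tuple:
    # a link and its reverse-complement reading are the same edge
    return min((a, oa, b, ob), (b, _flip(ob), a, _flip(oa)))


def _collect_links(
    tilings: dict[tuple[str, int], list[TilingStep]], names: dict[int, str]
) -> list[tuple[str, str, str, str]]:
    links: dict[tuple, tuple[str, str, str, str]] = {}
    for steps in tilings.values():
        for prev, cur in zip(steps, steps[1:]):
            a, oa = names[prev.unitig_id], prev.orientation
            b, ob = names[cur.unitig_id], cur.orientation
            links.setdefault(_link_key(a, oa, b, ob), (a, oa, b, ob))
    return [links[key] for key in sorted(links)]


def write_gfa(
    unitigs: Iterable[UnitigRecord],
    tilings: dict[tuple[str, int], list[TilingStep]],
    k: int,
    path: str | Path,
    version: int = 1,
) -> None:
    """Write the compacted graph as GFA1 (S/L/P) or GFA2 (S/E/O).

    Links are the edges of the compacted graph realised by consecutive
    tiling steps, deduplicated as unordered oriented pairs; every overlap
    is exactly k-1. One path/ordered group is written per input run,
    named ``<seq_id>:<start>``.
    """
    if version not in (1, 2):
        raise ValueError("GFA version must be 1 or 2")
    recs = sorted(unitigs, key=lambda r: r.id)
    names = {r.id: unitig_name(r.id) for r in recs}
    lengths = {unitig_name(r.id): r.length for r in recs}
    m = k - 1
    links = _collect_links(tilings, names)
    with open(path, "wt") as fh:
        if version == 1:
            fh.write("H\tVN:Z:1.0\n")
            for r in recs:
                fh.write(f"S\t{names[r.id]}\t{r.spelling}\tLN:i:{r.length}\n")
            for a, oa, b, ob in links:
                fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{m}M\n")
            for key in sorted(tilings):
                steps = tilings[key]
                seg_list = ",".join(f"{names[s.unitig_id]}{s.orientation}" for s in steps)
                overlaps = ",".join([f"{m}M"] * (len(steps) - 1)) if len(steps) > 1 else "*"
                fh.write(f"P\t{key[0]}:{key[1]}\t{seg_list}\t{overlaps}\n")
        else:
            fh.write("H\tVN:Z:2.0\n")
            for r in recs:
                fh.write(f"S\t{names[r.id]}\t{r.length}\t{r.spelling}\n")
            for a, oa, b, ob in links:
                la, lb = lengths[a], lengths[b]
                if oa == "+":
                    beg1, end1 = str(la - m), f"{la}$"
                else:
                    beg1, end1 = "0", str(m)
                if ob == "+":
                    beg2, end2 = "0", str(m)
                else:
                    beg2, end2 = str(lb - m), f"{lb}$"
                fh.write(f"E\t*\t{a}{oa}\t{b}{ob}\t{beg1}\t{end1}\t{beg2}\t{end2}\t{m}M\n")
            for key in sorted(tilings):
                steps = tilings[key]
                seg_list = " ".join(f"{names[s.unitig_id]}{s.orientation}" for s in steps)
                fh.write(f"O\t{key[0]}:{key[1]}\t{seg_list}\n")
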