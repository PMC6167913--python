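"""CDR-3 extraction and Chothia-style numbering from paired antibody chains.

Extraction uses the classic anchor-motif heuristic rather than a full
profile alignment: CDR-H3 is the span strictly between the conserved
framework-3 cysteine (the last Cys N-terminal of the J-segment motif) and
the ``WG.G`` motif of framework 4; CDR-L3 is bounded by the conserved Cys
and ``FG.G``.  This is deterministic and dependency-free, and adequate for
third loops; chains lacking the motifs are rejected rather than guessed at.

Chothia-style labels are attached for presentation: loops are mapped onto
the canonical third-loop positions (H: 95-102, L: 89-97), with insertion
codes A, B, C, ... added at the canonical insertion site near the loop
centre (after H100 / L95), and with deletions for short loops removed from
the centre outwards.
"""

from __future__ import annotations

import re
import logging
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ExtractionError, InputError, PairingError

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

PHENOTYPES = ("promiscuous", "non_promiscuous", "unknown")

# Framework-4 anchor motifs (heavy J: Trp-Gly-X-Gly; light J: Phe-Gly-X-Gly).
_J_MOTIF = {"H": re.compile(r"WG.G"), "L": re.compile(r"FG.G")}

# Canonical Chothia third-loop positions and the insertion site index within
# them (insertions go after H100 and after L95).
_CHOTHIA_BASE = {"H": list(range(95, 103)), "L": list(range(89, 98))}
_CHOTHIA_INSERT_AFTER = {"H": 100, "L": 95}


@dataclass(frozen=True)
class AntibodyRecord:
    """A paired heavy/light variable region with a binding phenotype label."""

    id: str
    heavy_seq: str
    light_seq: str
    phenotype: str = "unknown"

    def __post_init__(self):
        for name, seq in (("heavy", self.heavy_seq), ("light", self.light_seq)):
            bad = set(seq) - STANDARD_AA
            if bad:
                pos = min(i for i, c in enumerate(seq) if c in bad)
                raise InputError(
                    f"{self.id} {name} chain: non-standard residue "
                    f"{seq[pos]!r} at position {pos}")
        if self.phenotype not in PHENOTYPES:
            raise InputError(f"unknown phenotype label {self.phenotype!r}")

    def chain(self, chain: str) -> str:
        if chain == "H":
            return self.heavy_seq
        if chain == "L":
            return self.light_seq
        raise InputError(f"chain must be 'H' or 'L', got {chain!r}")


@dataclass(frozen=True)
class CDRRegion:
    """An extracted CDR-3 span with its Chothia presentation labels."""

    chain: str
    sequence: str
    start_index: int          # 0-based inclusive, in the parent chain
    end_index: int            # 0-based exclusive
    numbering: tuple          # Chothia labels, e.g. ('95', ..., '100B', ...)

    def __post_init__(self):
        if self.end_index - self.start_index != len(self.sequence):
            raise InputError("CDR span does not match its sequence length")
        if len(self.sequence) < 3:
            raise ExtractionError(
                f"CDR-{self.chain}3 shorter than 3 residues: {self.sequence!r}")
        if len(self.numbering) != len(self.sequence):
            raise InputError("numbering length must equal loop length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LengthDistribution:
    """Histogram of loop lengths over a record set."""

    counts: dict
    source_label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        return sum(k * v for k, v in self.counts.items()) / self.total

    @property
    def median(self) -> float:
        xs = sorted(k for k, v in self.counts.items() for _ in range(v))
        m = len(xs) // 2
        return float(xs[m]) if len(xs) % 2 else (xs[m - 1] + xs[m]) / 2.0


def chothia_labels(chain: str, length: int) -> tuple:
    """Chothia-style labels for a third loop of the given length.

    Insertions (A, B, C, ...) are placed after the canonical insertion
    position near the loop centre; deletions for short loops are taken from
    the centre outwards, mirroring how gaps are opened in structural
    numbering schemes.
    """
    base = _CHOTHIA_BASE[chain]
    anchor = _CHOTHIA_INSERT_AFTER[chain]
    n_base = len(base)
    if length >= n_base:
        n_ins = length - n_base
        pos = base.index(anchor)
        labels = [str(x) for x in base[:pos + 1]]
        labels += [f"{anchor}{chr(ord('A') + i)}" for i in range(n_ins)]
        labels += [str(x) for x in base[pos + 1:]]
        return tuple(labels)
    # Deletions: drop positions from the centre (insertion anchor) outwards,
    # alternating toward the C- then N-terminal side; deterministic.
    keep = list(base)
    pos = base.index(anchor)
    drop_order = sorted(base, key=lambda x: (abs(base.index(x) - pos),
                                             base.index(x) < pos))
    for d in drop_order[: n_base - length]:
        keep.remove(d)
    return tuple(str(x) for x in keep)


def extract_cdr3(record: AntibodyRecord, chain: str) -> CDRRegion:
    """Extract CDR-H3 or CDR-L3 from a record via its anchor motifs."""
    seq = record.chain(chain)
    motif = _J_MOTIF[chain]
    matches = list(motif.finditer(seq))
    if not matches:
        raise ExtractionError(
            f"{record.id} chain {chain}: J-segment motif "
            f"{motif.pattern!r} not found")
    if len(matches) > 1:
        logger.warning("%s chain %s: %d candidate %r anchors; using the "
                       "C-terminal-most", record.id, chain, len(matches),
                       motif.pattern)
    j_start = matches[-1].start()
    cys = seq.rfind("C", 0, j_start)
    if cys < 0:
        raise ExtractionError(
            f"{record.id} chain {chain}: no conserved Cys before the J motif")
    loop = seq[cys + 1:j_start]
    if len(loop) < 3:
        raise ExtractionError(
            f"{record.id} chain {chain}: loop between anchors too short "
            f"({loop!r})")
    return CDRRegion(chain=chain, sequence=loop, start_index=cys + 1,
                     end_index=j_start,
                     numbering=chothia_labels(chain, len(loop)))


def read_labelled_fasta(path) -> list:
    """Read paired chains from a FASTA with ``id|chain|phenotype`` headers."""
    path = Path(path)
    chains: dict = {}
    order: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2 or parts[1] not in ("H", "L"):
            raise PairingError(f"malformed header {rec.id!r}; "
                               "expected id|chain|phenotype")
        ab_id, chain = parts[0], parts[1]
        phenotype = parts[2] if len(parts) > 2 else "unknown"
        if phenotype not in PHENOTYPES:
            phenotype = "unknown"
        key = (ab_id, chain)
        if key in chains:
            raise PairingError(f"duplicate {chain} chain for id {ab_id!r}")
        if ab_id not in order:
            order.append(ab_id)
        chains[key] = (str(rec.seq).upper(), phenotype)
    records = []
    for ab_id in order:
        h = chains.get((ab_id, "H"))
        l = chains.get((ab_id, "L"))
        if h is None or l is None:
            missing = "H" if h is None else "L"
            raise PairingError(f"id {ab_id!r} lacks a {missing} chain")
        phenotype = h[1] if h[1] != "unknown" else l[1]
        records.append(AntibodyRecord(id=ab_id, heavy_seq=h[0],
                                      light_seq=l[0], phenotype=phenotype))
    return records


def write_labelled_fasta(records, path) -> None:
    """Write records in the ``id|chain|phenotype`` FASTA dialect."""
    out = []
    for r in records:
        out.append(SeqRecord(Seq(r.heavy_seq), id=f"{r.id}|H|{r.phenotype}",
                             description=""))
        out.append(SeqRecord(Seq(r.light_seq), id=f"{r.id}|L|{r.phenotype}",
                             description=""))
    SeqIO.write(out, str(path), "fasta")


def length_distribution(records, chain: str = "H",
                        source_label: str = "") -> LengthDistribution:
    """CDR-3 length histogram (Chothia-style anchor definition) for a set."""
    if not records:
        raise InputError("length_distribution requires at least one record")
    counts = Counter(len(extract_cdr3(r, chain)) for r in records)
    return LengthDistribution(counts=dict(sorted(counts.items())),
                              source_label=source_label)


def cdr_table(records, chains=("H", "L")) -> pd.DataFrame:
    """Tabulate extracted CDR-3 loops, one row per (record, chain)."""
    rows = []
    for r in records:
        for chain in chains:
            cdr = extract_cdr3(r, chain)
            rows.append({
                "id": r.id, "chain": chain, "phenotype": r.phenotype,
                "sequence": cdr.sequence, "length": len(cdr),
                "start": cdr.start_index, "end": cdr.end_index,
                "numbering": ",".join(cdr.numbering),
            })
    return pd.DataFrame(rows)
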