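"""β-sheet-forming propensity classes and stem/apex placement profiles.

Residues are binned into the five categorical propensity classes of the
Prevelige & Fasman scale (strong formers V/I/M down to the lone strong
breaker E).  A CDR-H3 loop is segmented into an N-terminal stem, an apex
(the central third, rounded outward so the apex is never shorter than
ceil(L/3)) and a C-terminal stem; hairpin-compatible loops keep breakers
out of the stems, which is summarized by ``stem_breaker_score``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

PROPENSITY_CLASSES: dict[str, frozenset] = {
    "strong_former": frozenset("VIM"),
    "former": frozenset("FYCTWLQ"),
    "indifferent": frozenset("RGAD"),
    "breaker": frozenset("HSKNP"),
    "strong_breaker": frozenset("E"),
}

CLASS_ORDER = ("strong_former", "former", "indifferent", "breaker",
               "strong_breaker")

_AA_TO_CLASS = {aa: label for label, members in PROPENSITY_CLASSES.items()
                for aa in members}

SEGMENTS = ("stem_n", "apex", "stem_c")


def classify(aa: str) -> str:
    """Propensity class of one amino acid."""
    try:
        return _AA_TO_CLASS[aa.upper()]
    except KeyError:
        raise InputError(f"no propensity class for residue {aa!r}")


def segment_bounds(length: int, apex_frac: float = 1.0 / 3.0) -> tuple:
    """(apex_start, apex_end) half-open bounds of the apex segment.

    The apex has length ceil(length * apex_frac), centred; when the two
    stems cannot be equal the N-terminal stem takes the extra residue.
    """
    if length < 3:
        raise InputError("loops shorter than 3 residues cannot be segmented")
    if not 0 < apex_frac <= 1:
        raise InputError("apex fraction must lie in (0, 1]")
    apex_len = math.ceil(length * apex_frac)
    start = math.ceil((length - apex_len) / 2)
    return start, start + apex_len


@dataclass
class PropensityProfile:
    """Per-position class and segment labels for one loop, with summaries."""

    sequence: str
    classes: tuple
    segments: tuple
    summary: pd.DataFrame          # counts, segments x classes

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_length(self, segment: str) -> int:
        return sum(1 for s in self.segments if s == segment)


def profile(cdr, apex_frac: float = 1.0 / 3.0) -> PropensityProfile:
    """Classify and segment every position of a CDR-3 loop."""
    seq = cdr.sequence if hasattr(cdr, "sequence") else str(cdr)
    a0, a1 = segment_bounds(len(seq), apex_frac)
    classes = tuple(classify(a) for a in seq)
    segments = tuple("stem_n" if i < a0 else "apex" if i < a1 else "stem_c"
                     for i in range(len(seq)))
    summary = pd.DataFrame(0, index=list(SEGMENTS), columns=list(CLASS_ORDER))
    for cls, seg in zip(classes, segments):
        summary.loc[seg, cls] += 1
    return PropensityProfile(sequence=seq, classes=classes,
                             segments=segments, summary=summary)


def stem_breaker_score(prof: PropensityProfile) -> float:
    """Fraction of stem residues that are breakers or strong breakers.

    0 marks fully hairpin-compatible stems; 1 marks stems made entirely of
    breakers.
    """
    stem_len = prof.segment_length("stem_n") + prof.segment_length("stem_c")
    if stem_len == 0:
        raise InputError("stem length is zero; score undefined")
    stems = prof.summary.loc[["stem_n", "stem_c"]]
    n_break = int(stems["breaker"].sum() + stems["strong_breaker"].sum())
    return n_break / stem_len


def profile_table(cdr_df: pd.DataFrame,
                  apex_frac: float = 1.0 / 3.0) -> pd.DataFrame:
    """Per-residue profile rows for a CDR table (as from cdr_annotation)."""
    rows = []
    for _, rec in cdr_df.iterrows():
        prof = profile(rec["sequence"], apex_frac)
        for i, (aa, cls, seg) in enumerate(zip(prof.sequence, prof.classes,
                                               prof.segments)):
            rows.append({"id": rec["id"], "chain": rec["chain"],
                         "position": i, "residue": aa, "class": cls,
                         "segment": seg})
    return pd.DataFrame(rows)


def summary_table(cdr_df: pd.DataFrame,
                  apex_frac: float = 1.0 / 3.0) -> pd.DataFrame:
    """Per-antibody segment/class counts and the stem breaker score."""
    rows = []
    for _, rec in cdr_df.iterrows():
        prof = profile(rec["sequence"], apex_frac)
        row = {"id": rec["id"], "chain": rec["chain"],
               "length": len(prof),
               "stem_breaker_score": stem_breaker_score(prof)}
        for seg in SEGMENTS:
            for cls in CLASS_ORDER:
                row[f"{seg}:{cls}"] = int(prof.summary.loc[seg, cls])
        rows.append(row)
    return pd.DataFrame(rows)
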