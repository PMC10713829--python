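"""HLA-repertoire analytics: pseudo-groove similarity, binder
classification, KL sequence logos, and population-frequency joins."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "AlleleRecord", "SimilarityScore", "MotifMatrix",
    "groove_similarity", "classify_binders", "kl_logo", "join_frequencies",
    "normalize_allele_name", "read_pseudo_sequences",
    "read_predictor_table", "read_frequency_table",
    "AMINO_ACIDS", "UNIPROT_BACKGROUND",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Swiss-Prot amino-acid composition (release 2023_01 statistics), renormalized
UNIPROT_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_total = sum(UNIPROT_BACKGROUND.values())
UNIPROT_BACKGROUND = {a: v / _total for a, v in UNIPROT_BACKGROUND.items()}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class AlleleRecord:
    allele: str
    pseudo_sequence: str = ""
    percent_rank_ba: float | None = None
    predicted_affinity_nm: float | None = None
    binder_class: str = ""  # 'strong' | 'weak' | 'non' | ''
    global_frequency_pct: float | None = None


@dataclass
class SimilarityScore:
    allele: str
    raw: int  # summed BLOSUM62 score against the reference
    normalized: float  # raw / reference self-score


@dataclass
class MotifMatrix:
    """Per-position probabilities, KL information (bits), letter heights."""

    probabilities: pd.DataFrame  # index positions 1..L, columns AMINO_ACIDS
    background: dict[str, float]
    information: np.ndarray  # bits per position
    heights: pd.DataFrame  # per-letter heights, proportional to p within a column

    @property
    def n_positions(self) -> int:
        return len(self.probabilities)


def blosum62(a: str, b: str) -> int:
    try:
        return int(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        raise KeyError(f"non-standard residue pair ({a!r}, {b!r})") from None


def groove_similarity(pseudo_sequences: dict[str, str],
                      reference: str) -> list[SimilarityScore]:
    """Position-wise BLOSUM62 scores of every allele's pseudo-groove
    sequence against the reference allele, self-score normalized.

    Sequences must be pre-aligned, gapless, and of equal length; the
    reference allele scores exactly 1.0.
    """
    if reference not in pseudo_sequences:
        raise KeyError(f"reference allele {reference!r} not in the set")
    ref_seq = pseudo_sequences[reference]
    self_score = sum(blosum62(c, c) for c in ref_seq)
    out = []
    for allele, seq in pseudo_sequences.items():
        if len(seq) != len(ref_seq):
            raise ValueError(
                f"{allele}: pseudo-sequence length {len(seq)} != "
                f"reference length {len(ref_seq)}")
        raw = sum(blosum62(a, b) for a, b in zip(seq, ref_seq))
        out.append(SimilarityScore(allele=allele, raw=raw,
                                   normalized=raw / self_score))
    return out


def classify_binders(records: list[AlleleRecord], strong_thr: float = 0.5,
                     weak_thr: float = 2.0) -> list[AlleleRecord]:
    """Assign strong/weak/non from %rank: strong iff rank <= strong_thr,
    weak iff strong_thr < rank <= weak_thr."""
    out = []
    for r in records:
        if r.percent_rank_ba is None:
            raise ValueError(f"{r.allele}: missing %rank")
        if r.percent_rank_ba < 0:
            raise ValueError(f"{r.allele}: negative %rank")
        if r.percent_rank_ba <= strong_thr:
            cls = "strong"
        elif r.percent_rank_ba <= weak_thr:
            cls = "weak"
        else:
            cls = "non"
        out.append(AlleleRecord(
            allele=r.allele, pseudo_sequence=r.pseudo_sequence,
            percent_rank_ba=r.percent_rank_ba,
            predicted_affinity_nm=r.predicted_affinity_nm,
            binder_class=cls, global_frequency_pct=r.global_frequency_pct))
    return out


def kl_logo(peptides: list[str] | pd.DataFrame,
            background: dict[str, float] | None = None) -> MotifMatrix:
    """Kullback-Leibler sequence-logo matrix.

    Per position, information I = sum_a p_a log2(p_a / q_a) (p_a = 0 terms
    contribute 0); letter heights are p_a * I, i.e. proportional to p
    within the column (positive letters only, Seq2Logo-style convention).
    """
    q = dict(background or {a: 1.0 / 20.0 for a in AMINO_ACIDS})
    if set(q) != set(AMINO_ACIDS):
        raise ValueError("background must cover the 20 standard residues")
    qv = np.array([q[a] for a in AMINO_ACIDS])
    if np.any(qv <= 0) or not math.isclose(qv.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must be strictly positive and sum to 1")

    if isinstance(peptides, pd.DataFrame):
        probs = peptides.copy()
        probs = probs[list(AMINO_ACIDS)]
    else:
        lengths = {len(p) for p in peptides}
        if len(lengths) != 1:
            raise ValueError(f"peptides have mixed lengths: {sorted(lengths)}")
        (length,) = lengths
        counts = np.zeros((length, 20))
        aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for p in peptides:
            for pos, aa in enumerate(p.upper()):
                if aa not in aa_index:
                    raise ValueError(f"non-standard residue {aa!r} in {p!r}")
                counts[pos, aa_index[aa]] += 1
        probs = pd.DataFrame(counts / counts.sum(axis=1, keepdims=True),
                             index=range(1, length + 1),
                             columns=list(AMINO_ACIDS))
    pmat = probs.to_numpy()
    if not np.allclose(pmat.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1 per position")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pmat > 0, pmat * np.log2(pmat / qv[None, :]), 0.0)
    info = terms.sum(axis=1)
    info = np.maximum(info, 0.0)
    heights = pd.DataFrame(pmat * info[:, None], index=probs.index,
                           columns=probs.columns)
    return MotifMatrix(probabilities=probs, background=q, information=info,
                       heights=heights)


def normalize_allele_name(name: str) -> str:
    """Canonical 'HLA-A*01:01' form from common spellings
    (A0101, HLA-A01:01, hla-a*01:01, A*01:01...)."""
    s = name.strip().upper().replace(" ", "")
    s = re.sub(r"^HLA-?", "", s)
    m = re.match(r"^([ABCEG])\*?(\d{2,3}):?(\d{2,3})(.*)$", s)
    if not m:
        return f"HLA-{s}"
    locus, grp, prot, rest = m.groups()
    return f"HLA-{locus}*{int(grp):02d}:{int(prot):02d}{rest}"


def join_frequencies(binders: list[AlleleRecord],
                     freq_table: pd.DataFrame) -> list[AlleleRecord]:
    """Left-join population frequencies onto binder records and sort
    descending by frequency (stable; missing frequencies last).

    ``freq_table`` needs columns ``allele`` and ``frequency_pct``; duplicate
    allele rows (after name normalization) are an error.
    """
    required = {"allele", "frequency_pct"}
    missing = required - set(freq_table.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    norm = freq_table["allele"].map(normalize_allele_name)
    dupes = sorted(norm[norm.duplicated()].unique())
    if dupes:
        raise ValueError(f"duplicate allele rows in frequency table: {dupes}")
    lut = dict(zip(norm, freq_table["frequency_pct"].astype(float)))
    joined = []
    for r in binders:
        freq = lut.get(normalize_allele_name(r.allele))
        joined.append(AlleleRecord(
            allele=r.allele, pseudo_sequence=r.pseudo_sequence,
            percent_rank_ba=r.percent_rank_ba,
            predicted_affinity_nm=r.predicted_affinity_nm,
            binder_class=r.binder_class,
            global_frequency_pct=None if freq is None else float(freq)))
    order = sorted(
        range(len(joined)),
        key=lambda i: (joined[i].global_frequency_pct is None,
                       -(joined[i].global_frequency_pct or 0.0)))
    return [joined[i] for i in order]


# ------------------------------------------------------------------ readers

def read_pseudo_sequences(path: str | Path,
                          loci_prefixes: tuple[str, ...] | None = None,
                          ) -> dict[str, str]:
    """Whitespace-delimited 'allele pseudo-sequence' file (one per line)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"malformed pseudo-sequence line: {raw!r}")
        allele, seq = fields[0], fields[1]
        if loci_prefixes and not allele.startswith(loci_prefixes):
            continue
        out[allele] = seq
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise ValueError(f"pseudo-sequence lengths differ: {sorted(lengths)}")
    return out


def read_predictor_table(path: str | Path) -> list[AlleleRecord]:
    """Binder-prediction table: CSV/TSV with columns ``allele``, ``peptide``
    (optional), ``percent_rank_ba``, and optional ``affinity_nm``."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    if "allele" not in cols or "percent_rank_ba" not in cols:
        raise ValueError("predictor table needs 'allele' and "
                         "'percent_rank_ba' columns")
    records = []
    for row in df.itertuples():
        aff = getattr(row, cols["affinity_nm"], None) \
            if "affinity_nm" in cols else None
        records.append(AlleleRecord(
            allele=str(getattr(row, cols["allele"])),
            percent_rank_ba=float(getattr(row, cols["percent_rank_ba"])),
            predicted_affinity_nm=None if aff is None or pd.isna(aff)
            else float(aff)))
    return records


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    """Allele-frequency CSV with columns allele, frequency_pct
    (sample_size optional)."""
    df = pd.read_csv(path)
    if "allele" not in df.columns or "frequency_pct" not in df.columns:
        raise ValueError("frequency table needs 'allele' and "
                         "'frequency_pct' columns")
    return df
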