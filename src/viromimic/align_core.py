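"""Translated homology search with Karlin-Altschul statistics.

This module is the search engine behind the pipeline's tBLASTn- and
BLASTp-style steps: six-frame translation, low-complexity masking, seeded
word matching with ungapped x-drop extension, banded gapped refinement, and
conversion of raw alignment scores to bit scores and E-values.

Statistics
----------
Raw local-alignment scores are converted with the ungapped Karlin-Altschul
parameters of the scoring system: ``lambda`` is the unique positive root of
``sum_ij p_i p_j exp(lambda * s_ij) = 1``, ``K`` comes from the standard
series for the lattice case, and ``H`` is the relative entropy per aligned
pair.  The E-value of a raw score S against a database of ``n`` residues in
``c`` sequences is::

    E = K * m' * n' * exp(-lambda * S)

with the usual edge-effect correction ``l = round(ln(K m n) / H)``,
``m' = max(1, m - l)``, ``n' = max(c, n - c*l)``.  Ungapped parameters are
applied to (mildly) gapped scores, which is conservative in the sense of
early gapped BLAST; user-supplied gapped (lambda, K) are accepted wherever a
:class:`KAParams` is taken.  Composition-based score adjustment is not
implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .seqio import HitTable

__all__ = [
    "ALPHABET",
    "SubstitutionMatrix",
    "KAParams",
    "AlignmentHit",
    "SearchParams",
    "LocalAlignment",
    "blosum62",
    "compute_ka_params",
    "translate",
    "reverse_complement",
    "mask_low_complexity",
    "smith_waterman_affine",
    "seeded_search",
    "evalue",
    "bit_score",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X*"  # codes 0..21; 22 is the database sentinel
X_CODE = 20
STOP_CODE = 21

_CODE_OF = {c: i for i, c in enumerate(ALPHABET)}
_ENCODE_TABLE = np.full(256, X_CODE, dtype=np.int8)
for _c, _i in _CODE_OF.items():
    _ENCODE_TABLE[ord(_c)] = _i

# Robinson & Robinson (1991) amino-acid background frequencies, the standard
# background used for ungapped protein-search statistics (alphabetical order).
ROBINSON_BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def encode(seq: str) -> np.ndarray:
    """Encode a protein string into int8 codes (unknown residues -> X)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class SubstitutionMatrix:
    """A symmetric residue substitution matrix plus background frequencies.

    ``background`` covers the leading letters of ``alphabet`` that have
    non-zero background probability (extra letters such as X and the stop
    symbol are treated as zero-probability and excluded from the score
    statistics).
    """

    name: str
    alphabet: str
    scores: np.ndarray  # (n, n) int32
    background: np.ndarray  # (k,) float64, k <= n, sums to 1

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        self.scores = np.asarray(self.scores, dtype=np.int32)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over the alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        k = self.background.shape[0]
        if k < 2 or k > n:
            raise ValueError("background length must cover part of the alphabet")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        core = self.scores[:k, :k].astype(np.float64)
        expected = float(self.background @ core @ self.background)
        if expected >= 0:
            raise ValueError("expected score must be negative")
        if core.max() <= 0:
            raise ValueError("matrix needs at least one positive score")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])

    def encode_seq(self, seq: str) -> np.ndarray:
        """Encode a sequence into this matrix's residue codes."""
        if self.alphabet == ALPHABET:
            return encode(seq)
        table = {c: i for i, c in enumerate(self.alphabet)}
        try:
            return np.array([table[c] for c in seq], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} not in matrix alphabet"
            ) from exc

    def kernel_matrix(self) -> np.ndarray:
        """23x23 int32 matrix including the sentinel row/column."""
        n = len(self.alphabet)
        S = np.full((23, 23), np.int32(-1024), dtype=np.int32)
        S[:n, :n] = self.scores
        return S


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 over the 22-letter alphabet with the standard background.

    X scores -1 against everything and the stop symbol '*' scores -4 against
    everything, so translated alignments may pass through stop codons at a
    penalty (no reading-frame/ORF requirement).
    """
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    scores = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            scores[i, j] = int(bl[a, b])
    scores[X_CODE, :] = -1
    scores[:, X_CODE] = -1
    scores[STOP_CODE, :] = -4
    scores[:, STOP_CODE] = -4
    bg = np.array([ROBINSON_BACKGROUND[a] for a in AA20], dtype=np.float64)
    bg = bg / bg.sum()
    return SubstitutionMatrix(name="BLOSUM62", alphabet=ALPHABET,
                              scores=scores, background=bg)


@dataclass(frozen=True)
class KAParams:
    """Karlin-Altschul statistical parameters of a scoring system."""

    lambda_: float  # nats per raw-score unit
    K: float
    H: float  # relative entropy, nats per aligned pair

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or not (0 < self.K < 1) or self.H <= 0:
            raise ValueError(f"invalid Karlin-Altschul parameters: {self}")


def compute_ka_params(matrix: SubstitutionMatrix, series_tol: float = 1e-12) -> KAParams:
    """Ungapped (lambda, K, H) for a substitution matrix and background.

    ``lambda`` is found by root bracketing to near machine precision; ``K``
    uses the classical lattice-case series, truncated once a term drops
    below ``series_tol``.
    """
    k = matrix.background.shape[0]
    p = matrix.background
    core = matrix.scores[:k, :k]
    smin = int(core.min())
    smax = int(core.max())
    # distribution of the per-pair step score under the background
    probs = np.zeros(smax - smin + 1, dtype=np.float64)
    np.add.at(probs, (core - smin).ravel(), np.outer(p, p).ravel())
    svals = np.arange(smin, smax + 1, dtype=np.float64)
    expected = float(probs @ svals)
    if expected >= 0:
        raise ValueError(
            f"expected score {expected:.4f} is non-negative; no positive lambda root"
        )

    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * svals)) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-300, rtol=8.9e-16))
    H = lam * float(probs @ (svals * np.exp(lam * svals)))

    support = np.nonzero(probs > 0)[0] + smin
    delta = int(np.gcd.reduce(np.abs(support[support != 0])))

    # sigma = sum_k (1/k) * E[min(1, exp(lambda * S_k))] over k-step sums
    sigma = 0.0
    dist = probs.copy()
    offset = smin  # dist[i] = P(S_k = offset + i)
    for kk in range(1, 2000):
        if kk > 1:
            dist = np.convolve(dist, probs)
            offset += smin
        vals = np.arange(offset, offset + dist.shape[0], dtype=np.float64)
        neg = vals < 0
        term = float(dist[neg] @ np.exp(lam * vals[neg]) + dist[~neg].sum()) / kk
        sigma += term
        if term < series_tol:
            break
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return KAParams(lambda_=lam, K=K, H=H)


# --- translation ------------------------------------------------------------

def _build_codon_table() -> Dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


_CODON_TABLE = _build_codon_table()
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_FRAMES = (1, 2, 3, -1, -2, -3)


def reverse_complement(nuc: str) -> str:
    return nuc.translate(_COMPLEMENT)[::-1]


def translate(nuc: str, frame: int) -> str:
    """Translate one reading frame; codons with N (or any ambiguity) become X.

    Minus frames translate the reverse complement offset by ``|frame| - 1``;
    the trailing partial codon is dropped and stop codons are emitted as '*'.
    """
    if frame not in VALID_FRAMES:
        raise ValueError(f"frame must be one of {VALID_FRAMES}, got {frame}")
    seq = reverse_complement(nuc) if frame < 0 else nuc
    seq = seq[abs(frame) - 1:]
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


def mask_low_complexity(protein: str, window: int = 12,
                        entropy_thresh: float = 2.0) -> str:
    """Replace residues inside low-entropy windows with X.

    Every residue covered by at least one length-``window`` window whose
    Shannon entropy (base 2, observed frequencies) is below
    ``entropy_thresh`` is masked.  Proteins shorter than the window are
    returned unchanged.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    L = len(protein)
    if L < window:
        return protein
    counts: Dict[str, int] = {}
    for ch in protein[:window]:
        counts[ch] = counts.get(ch, 0) + 1

    def entropy() -> float:
        h = 0.0
        for c in counts.values():
            if c:
                f = c / window
                h -= f * math.log2(f)
        return h

    masked = np.zeros(L, dtype=bool)
    for start in range(L - window + 1):
        if start > 0:
            old = protein[start - 1]
            counts[old] -= 1
            new = protein[start + window - 1]
            counts[new] = counts.get(new, 0) + 1
        if entropy() < entropy_thresh:
            masked[start:start + window] = True
    if not masked.any():
        return protein
    chars = list(protein)
    for i in np.nonzero(masked)[0]:
        chars[i] = "X"
    return "".join(chars)


# --- local alignment --------------------------------------------------------

@dataclass
class LocalAlignment:
    """Best-scoring local alignment; coordinates are 0-based half-open."""

    raw_score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _traceback(a_codes, b_codes, bi, bj, ptrH, ptrE, ptrF):
    """Reconstruct the alignment path; op codes 0=diag, 1=up, 2=left."""
    ops = []
    i, j = bi, bj
    state = 0  # 0=H, 1=E(up), 2=F(left)
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append(0)
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptrE[i, j]
            ops.append(1)
            i -= 1
            if opened:
                state = 0
        else:
            opened = ptrF[i, j]
            ops.append(2)
            j -= 1
            if opened:
                state = 0
    ops.reverse()
    return i, j, ops


def _ops_to_strings(a_codes, b_codes, ai, bj, ops,
                    alphabet: str = ALPHABET) -> Tuple[str, str]:
    sa, sb = [], []
    i, j = ai, bj
    for op in ops:
        if op == 0:
            sa.append(alphabet[a_codes[i]])
            sb.append(alphabet[b_codes[j]])
            i += 1
            j += 1
        elif op == 1:
            sa.append(alphabet[a_codes[i]])
            sb.append("-")
            i += 1
        else:
            sa.append("-")
            sb.append(alphabet[b_codes[j]])
            j += 1
    return "".join(sa), "".join(sb)


def smith_waterman_affine(
    a: str,
    b: str,
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Optimal local alignment under affine gap costs.

    Opening a gap costs ``gap_open + gap_extend`` for its first residue and
    ``gap_extend`` for each further residue.  Traceback ties prefer
    diagonal, then up, then left.  An all-negative comparison yields score 0
    and an empty alignment.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    matrix = matrix or blosum62()
    ac = matrix.encode_seq(a)
    bc = matrix.encode_seq(b)
    S = matrix.kernel_matrix()
    best, bi, bj, H, ptrH, ptrE, ptrF = _kernels.sw_full(
        ac, bc, S, gap_open, gap_extend
    )
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    ai, bjj, ops = _traceback(ac, bc, bi, bj, ptrH, ptrE, ptrF)
    sa, sb = _ops_to_strings(ac, bc, ai, bjj, ops, matrix.alphabet)
    return LocalAlignment(int(best), ai, bi, bjj, bj, sa, sb)


# --- E-values ---------------------------------------------------------------

def bit_score(raw_score: float, ka: KAParams) -> float:
    return (ka.lambda_ * raw_score - math.log(ka.K)) / math.log(2.0)


def _edge_length(m: int, n: int, ka: KAParams) -> int:
    l = int(round(math.log(ka.K * m * n) / ka.H))
    return max(0, l)


def evalue(
    raw_score: float,
    query_len_aa: int,
    db_len: int,
    ka: KAParams,
    n_seqs: int = 1,
    edge_correction: bool = True,
) -> float:
    """Expected number of chance HSPs scoring >= raw_score.

    ``db_len`` is the total residue count of the search space (for
    translated searches: summed over all six frames of every fragment) and
    ``n_seqs`` the number of database sequences used in the edge correction.
    """
    if raw_score <= 0:
        raise ValueError("raw_score must be positive")
    m, n = query_len_aa, db_len
    l = _edge_length(m, n, ka) if edge_correction else 0
    m_eff = max(1, m - l)
    n_eff = max(n_seqs, n - n_seqs * l)
    return ka.K * m_eff * n_eff * math.exp(-ka.lambda_ * raw_score)


def min_score_for_evalue(
    target_evalue: float, query_len_aa: int, db_len: int, ka: KAParams,
    n_seqs: int = 1,
) -> int:
    """Smallest raw score whose E-value is <= target_evalue."""
    m, n = query_len_aa, db_len
    l = _edge_length(m, n, ka)
    m_eff = max(1, m - l)
    n_eff = max(n_seqs, n - n_seqs * l)
    s = math.log(ka.K * m_eff * n_eff / target_evalue) / ka.lambda_
    return max(1, math.ceil(s))


# --- seeded search ----------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Heuristic search parameters (BLAST-era protein-search defaults)."""

    word_size: int = 3
    neighbor_thresh: int = 11
    x_drop: int = 20
    gap_open: int = 11
    gap_extend: int = 1
    evalue_report_max: float = 10.0
    mask_window: int = 12
    mask_entropy: float = 2.0
    # HSPs whose ungapped E-value exceeds this are not carried into the
    # gapped stage; a multiple of evalue_report_max keeps borderline HSPs.
    gap_trigger_evalue: float = 50.0

    def __post_init__(self) -> None:
        numeric = (self.word_size, self.neighbor_thresh, self.x_drop,
                   self.gap_open, self.gap_extend, self.evalue_report_max,
                   self.mask_window, self.mask_entropy, self.gap_trigger_evalue)
        if any(v <= 0 for v in numeric):
            raise ValueError("all search parameters must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass
class AlignmentHit:
    """One HSP between a query protein and a (translated) subject."""

    query_id: str
    subject_id: str
    frame: int  # {-3..-1, +1..+3}; 0 for protein-protein
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_openings: int
    q_start: int  # 1-based inclusive, protein coordinates
    q_end: int
    s_start: int  # 1-based inclusive; nucleotide coords, start > end on minus strand
    s_end: int
    evalue: float
    bit_score: float
    raw_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("percent identity must lie in [0, 100]")


class _SubjectFrame:
    """One translated frame of a subject, located inside the packed database."""

    __slots__ = ("subject_id", "frame", "db_start", "length", "nt_len")

    def __init__(self, subject_id, frame, db_start, length, nt_len):
        self.subject_id = subject_id
        self.frame = frame
        self.db_start = db_start
        self.length = length
        self.nt_len = nt_len


def _subject_id(subject) -> str:
    return getattr(subject, "fragment_id", None) or subject.id


def _build_database(subjects, mode: str):
    """Pack all subject frames into one sentinel-separated code array."""
    parts: List[np.ndarray] = []
    frames: List[_SubjectFrame] = []
    pos = 0
    sentinel = np.array([_kernels.SENTINEL], dtype=np.int8)
    for subj in subjects:
        sid = _subject_id(subj)
        if mode == "tblastn":
            for fr in VALID_FRAMES:
                prot = translate(subj.residues, fr)
                if not prot:
                    continue
                codes = encode(prot)
                frames.append(_SubjectFrame(sid, fr, pos, len(prot),
                                            len(subj.residues)))
                parts.append(codes)
                parts.append(sentinel)
                pos += len(prot) + 1
        else:
            codes = encode(subj.residues)
            frames.append(_SubjectFrame(sid, 0, pos, len(subj.residues), 0))
            parts.append(codes)
            parts.append(sentinel)
            pos += len(subj.residues) + 1
    if parts:
        db = np.concatenate(parts).astype(np.int8)
    else:
        db = np.zeros(0, dtype=np.int8)
    return db, frames


def _subject_coords(sf: _SubjectFrame, aa_start: int, aa_end: int) -> Tuple[int, int]:
    """Map an aa span on a subject frame to 1-based inclusive output coords."""
    if sf.frame == 0:
        return aa_start + 1, aa_end
    f = abs(sf.frame)
    if sf.frame > 0:
        return (f - 1) + 3 * aa_start + 1, (f - 1) + 3 * aa_end
    L = sf.nt_len
    return L - (f - 1) - 3 * aa_start, L - (f - 1) - 3 * aa_end + 1


def _alignment_stats(ops, a_codes, b_codes, ai, bj):
    matches = mismatches = gaps = 0
    in_gap = False
    i, j = ai, bj
    for op in ops:
        if op == 0:
            if a_codes[i] == b_codes[j]:
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
            in_gap = False
        else:
            if not in_gap:
                gaps += 1
                in_gap = True
            if op == 1:
                i += 1
            else:
                j += 1
    return matches, mismatches, gaps


_GAP_WINDOW_MARGIN = 64


def seeded_search(
    queries: Sequence,
    subjects: Sequence,
    params: SearchParams = SearchParams(),
    matrix: Optional[SubstitutionMatrix] = None,
    mode: str = "tblastn",
    ka: Optional[KAParams] = None,
) -> HitTable:
    """Search protein queries against nucleotide (tblastn) or protein (blastp)
    subjects.

    Queries are hard-masked for low complexity, seeds are word matches
    scoring at least ``neighbor_thresh``, extensions are ungapped x-drop
    followed by gapped refinement in a window around each HSP, and E-values
    are computed against the entire translated search space.  Within each
    (query, subject, frame) the best-scoring mutually non-overlapping HSPs
    are kept (greedy, discarding HSPs overlapping a kept one by more than
    half their query span).  The result is fully deterministic.
    """
    if mode not in ("tblastn", "blastp"):
        raise ValueError(f"mode must be 'tblastn' or 'blastp', got {mode!r}")
    matrix = matrix or blosum62()
    if ka is None:
        ka = compute_ka_params(matrix)
    if not queries or not subjects:
        return HitTable([])

    db, sframes = _build_database(subjects, mode)
    if db.shape[0] == 0:
        return HitTable([])
    n_total = sum(sf.length for sf in sframes)
    # Edge-effect correction counts the sequences actually searched: in
    # translated mode each fragment contributes six short frame sequences,
    # and an HSP must fit inside one of them.
    n_seqs = len(sframes) if mode == "tblastn" else len(subjects)
    S = matrix.kernel_matrix()
    w = params.word_size

    codes = _kernels.word_codes(db, w)
    vocab = _kernels.NLETTERS ** w
    valid = codes >= 0
    positions = np.nonzero(valid)[0].astype(np.int64)
    cvalid = codes[valid]
    counts = np.bincount(cvalid, minlength=vocab)
    word_starts = np.zeros(vocab + 1, dtype=np.int64)
    np.cumsum(counts, out=word_starts[1:])
    order = np.argsort(cvalid, kind="stable")
    word_pos = positions[order]

    frame_starts = np.array([sf.db_start for sf in sframes], dtype=np.int64)

    hits: List[AlignmentHit] = []
    for q_index, query in enumerate(queries):
        masked = mask_low_complexity(query.residues, params.mask_window,
                                     params.mask_entropy)
        qc = encode(masked)
        m = len(masked)
        min_keep = min_score_for_evalue(params.gap_trigger_evalue, m, n_total,
                                        ka, n_seqs)
        cap = 20000
        while True:
            out = np.empty((cap, 5), dtype=np.int64)
            diag_cover = np.full(db.shape[0] + m + 1, -1, dtype=np.int64)
            n_hsp = _kernels.seed_scan(
                qc, db, word_starts, word_pos, S, w, params.neighbor_thresh,
                params.x_drop, min_keep, diag_cover, out,
            )
            if n_hsp >= 0:
                break
            cap *= 4
        if n_hsp == 0:
            continue

        # gapped refinement of each retained ungapped HSP
        per_frame: Dict[int, List] = {}
        seen = set()
        for r in range(n_hsp):
            qs, qe, ss, se, _score = out[r]
            fi = int(np.searchsorted(frame_starts, ss, side="right") - 1)
            sf = sframes[fi]
            fs, fe = sf.db_start, sf.db_start + sf.length
            qw0 = max(0, qs - _GAP_WINDOW_MARGIN)
            qw1 = min(m, qe + _GAP_WINDOW_MARGIN)
            sw0 = max(fs, ss - _GAP_WINDOW_MARGIN)
            sw1 = min(fe, se + _GAP_WINDOW_MARGIN)
            best, bi, bj, H, ptrH, ptrE, ptrF = _kernels.sw_full(
                qc[qw0:qw1], db[sw0:sw1], S, params.gap_open, params.gap_extend
            )
            if best <= 0:
                continue
            ai, bjj, ops = _traceback(qc[qw0:qw1], db[sw0:sw1], bi, bj,
                                      ptrH, ptrE, ptrF)
            g_qs, g_qe = qw0 + ai, qw0 + bi
            g_ss, g_se = sw0 + bjj, sw0 + bj
            key = (g_qs, g_qe, g_ss, g_se)
            if key in seen:
                continue
            seen.add(key)
            matches, mismatches, gaps = _alignment_stats(
                ops, qc, db, g_qs, g_ss
            )
            per_frame.setdefault(fi, []).append(
                (int(best), g_qs, g_qe, g_ss, g_se, len(ops), matches,
                 mismatches, gaps)
            )

        for fi, hsps in sorted(per_frame.items()):
            sf = sframes[fi]
            hsps.sort(key=lambda h: (-h[0], h[1], h[3]))
            kept: List = []
            for cand in hsps:
                span = cand[2] - cand[1]
                clash = False
                for k in kept:
                    ov = min(cand[2], k[2]) - max(cand[1], k[1])
                    if ov > 0.5 * span:
                        clash = True
                        break
                if not clash:
                    kept.append(cand)
            for score, g_qs, g_qe, g_ss, g_se, ncols, matches, mism, gaps in kept:
                e = evalue(score, m, n_total, ka, n_seqs)
                if e > params.evalue_report_max:
                    continue
                aa_s = g_ss - sf.db_start
                aa_e = g_se - sf.db_start
                s_start, s_end = _subject_coords(sf, aa_s, aa_e)
                hits.append(
                    AlignmentHit(
                        query_id=query.id,
                        subject_id=sf.subject_id,
                        frame=sf.frame,
                        pct_identity=100.0 * matches / ncols,
                        aln_len=ncols,
                        mismatches=mism,
                        gap_openings=gaps,
                        q_start=g_qs + 1,
                        q_end=g_qe,
                        s_start=s_start,
                        s_end=s_end,
                        evalue=e,
                        bit_score=bit_score(score, ka),
                        raw_score=score,
                    )
                )

    query_order = {q.id: i for i, q in enumerate(queries)}
    hits.sort(key=lambda h: (query_order[h.query_id], h.evalue, h.subject_id,
                             h.frame, h.q_start))
    return HitTable(hits)
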