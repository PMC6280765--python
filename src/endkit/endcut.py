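"""Detection of small-RNA-guided cleavage sites from 5'-end signal.

A plant miRNA or tasiRNA guides endonucleolytic cleavage of its target
between the target bases paired to sRNA positions 10 and 11 (counting from
the sRNA 5' end), so the 5'-monophosphorylated 3' fragment leaves a 5P read
pile whose 5' end sits exactly opposite sRNA position 10.

For every sRNA, candidate target sites are enumerated on each transcript by
antisense duplex alignment allowing Watson-Crick pairs, G:U wobbles,
mismatches, and a single-nucleotide bulge on either side.  Duplexes are
scored with the position-weighted mismatch penalty of Allen et al. (mismatch
1.0, G:U 0.5, bulged nucleotide 1.0, penalties doubled at sRNA positions
2-13); lower is better.

Significance is assessed against an empirical null: each sRNA is shuffled
(composition-preserving) many times, the shuffles are processed identically,
and the pooled null fold changes and Allen scores form the ECDFs against
which the observed sites are ranked.  Per-site one-sided p-values for fold
change and Allen score are combined with Fisher's method (chi-square, 4 df)
and adjusted across all sites in the library by Benjamini-Hochberg.  A site
is called significant when adjusted p < 0.05, fold change > 1.0, and the
site is supported by at least one read per ten million transcriptome-mapped
reads (RPTM >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .endmask import TranscriptTrack

MIN_SRNA_LEN = 15
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PAD = 4  # sentinel for out-of-bounds / ambiguous bases

#: pair penalties in the reverse-complement frame: row = revcomp(sRNA) base,
#: column = target base.  Equal bases pair Watson-Crick with the sRNA (0.0);
#: (C,T) and (A,G) correspond to sRNA G:U(T) and U(T):G wobbles (0.5);
#: anything involving the pad sentinel is effectively forbidden.
_PENALTY = np.full((5, 5), 1.0, dtype=np.float32)
np.fill_diagonal(_PENALTY, 0.0)
_PENALTY[1, 3] = 0.5  # sRNA G : target U
_PENALTY[0, 2] = 0.5  # sRNA U : target G
_PENALTY[_PAD, :] = _PENALTY[:, _PAD] = 1e3

_BULGE_PENALTY = 1.0
CORE_START, CORE_END = 2, 13  # sRNA positions with doubled penalties (inclusive)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, _PAD) for c in seq.upper()), dtype=np.int8, count=len(seq))


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, _PAD).astype(np.int8)
    return out[::-1] if out.ndim == 1 else out[:, ::-1]


def _position_weights(m: int) -> np.ndarray:
    """Penalty multipliers indexed by reverse-complement frame position q,
    where q corresponds to sRNA position p = m - q (1-based from the 5' end)."""
    p = m - np.arange(m)
    return np.where((p >= CORE_START) & (p <= CORE_END), 2.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Shuffling
# ---------------------------------------------------------------------------

def shuffle_srna(seq: str, n: int = 1000, seed: int = 0) -> List[str]:
    """n composition-preserving permutations of ``seq`` (reproducible)."""
    if len(seq) < MIN_SRNA_LEN:
        raise ValueError(f"sRNA shorter than {MIN_SRNA_LEN} nt: {seq!r}")
    if n < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq.upper()))
    return ["".join(letters[rng.permutation(len(letters))]) for _ in range(n)]


# ---------------------------------------------------------------------------
# Allen scoring
# ---------------------------------------------------------------------------

def allen_score(states: Sequence[str], target_bulges: Sequence[int] = ()) -> float:
    """Score a duplex from per-sRNA-position pairing states.

    ``states[i]`` describes sRNA position i+1 (5'->3'): one of ``match``,
    ``gu``, ``mismatch``, ``bulge`` (an unpaired sRNA base).  Bulged target
    nucleotides are given by ``target_bulges`` as the sRNA position after
    which the extra target base is inserted.  Penalties: mismatch 1.0, G:U
    0.5, bulge 1.0; doubled at sRNA positions 2-13.
    """
    per_state = {"match": 0.0, "gu": 0.5, "mismatch": 1.0, "bulge": _BULGE_PENALTY}
    total = 0.0
    for i, st in enumerate(states):
        if st not in per_state:
            raise ValueError(f"unknown pairing state {st!r}")
        p = i + 1
        total += per_state[st] * (2.0 if CORE_START <= p <= CORE_END else 1.0)
    for p in target_bulges:
        total += _BULGE_PENALTY * (2.0 if CORE_START <= p <= CORE_END else 1.0)
    return total


# ---------------------------------------------------------------------------
# Target-site scanning
# ---------------------------------------------------------------------------

@dataclass
class TargetSite:
    """A predicted sRNA-target duplex on one transcript."""

    srna_name: str
    transcript_id: str
    start: int  # 5'-most target base of the duplex (transcript coordinate)
    cleavage_offset: int  # 5' end of the 3' cleavage fragment
    allen_score: float
    states: List[str] = field(default_factory=list)
    target_bulge_after: Optional[int] = None


try:  # the scan kernel is compiled when numba is available (it always is in
    # the supported environment); the numpy fallback keeps the module usable
    # elsewhere at reduced speed
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco(args[0]) if args and callable(args[0]) else deco


@_njit(cache=False, fastmath=True)
def _scan_kernel(rc_codes, target, w, penalty, bulge_pen, max_score,
                 out_v, out_o, out_sc, out_cl, out_kind):  # pragma: no cover
    n, m = rc_codes.shape
    L = target.size
    Lw = L - m + 1
    qstar = m - 10
    count = 0
    suf1 = np.empty(m + 1, np.float64)
    sufm1 = np.empty(m + 1, np.float64)
    for s in range(n):
        row = rc_codes[s]
        for o in range(Lw):
            # suffix sums of the +1 / -1 frame penalties
            suf1[m] = 0.0
            sufm1[m] = 0.0
            for q in range(m - 1, -1, -1):
                ti = o + q + 1
                p1 = penalty[row[q], target[ti]] if ti < L else 1e3
                suf1[q] = suf1[q + 1] + w[q] * p1
                ti = o + q - 1
                pm1 = penalty[row[q], target[ti]] if ti >= 0 else 1e3
                sufm1[q] = sufm1[q + 1] + w[q] * pm1
            pre = 0.0
            best = 1e30
            best_kind = 0
            best_j = 0
            for j in range(m):
                if j >= 1:
                    tb = pre + w[j] * bulge_pen + suf1[j]
                    if tb < best:
                        best, best_kind, best_j = tb, 1, j
                sb = pre + w[j] * bulge_pen + sufm1[j + 1]
                if sb < best:
                    best, best_kind, best_j = sb, 2, j
                pre += w[j] * penalty[row[j], target[o + j]]
            if pre <= best:  # prefer the simplest alignment shape on ties
                best, best_kind = pre, 0
            if best <= max_score:
                cl = o + qstar
                if best_kind == 1 and qstar >= best_j:
                    cl += 1
                elif best_kind == 2 and qstar > best_j:
                    cl -= 1
                out_v[count] = s
                out_o[count] = o
                out_sc[count] = best
                out_cl[count] = cl
                out_kind[count] = best_kind
                count += 1
    return count


def _scan_batch(
    rc_codes: np.ndarray,
    target: np.ndarray,
    max_score: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Score every duplex of every variant against one transcript.

    ``rc_codes`` has shape (n_variants, m): reverse-complemented sRNA
    variants.  For each (variant, duplex start offset) the best-scoring
    alignment shape — ungapped, one bulged target base, or one bulged sRNA
    base — is taken, and alignments with score <= max_score are returned as
    flat arrays (variant, offset, score, cleavage position, kind) with
    kind 0 = ungapped, 1 = target bulge, 2 = sRNA bulge.
    """
    n, m = rc_codes.shape
    L = int(target.size)
    Lw = L - m + 1
    empty = (np.empty(0, np.int64),) * 2 + (np.empty(0, np.float64),) + (np.empty(0, np.int64),) * 2
    if Lw <= 0 or n == 0:
        return empty
    w = _position_weights(m).astype(np.float64)
    cap = n * Lw
    out_v = np.empty(cap, np.int64)
    out_o = np.empty(cap, np.int64)
    out_sc = np.empty(cap, np.float64)
    out_cl = np.empty(cap, np.int64)
    out_kind = np.empty(cap, np.int64)
    count = _scan_kernel(
        rc_codes.astype(np.int64), target.astype(np.int64), w,
        _PENALTY.astype(np.float64), float(_BULGE_PENALTY), float(max_score),
        out_v, out_o, out_sc, out_cl, out_kind,
    )
    return (out_v[:count].copy(), out_o[:count].copy(), out_sc[:count].copy(),
            out_cl[:count].copy(), out_kind[:count].copy())


def _dedupe_by_site(
    variants: np.ndarray, cleavages: np.ndarray, scores: np.ndarray
) -> np.ndarray:
    """Indices of the best-scoring alignment per (variant, cleavage site)."""
    if variants.size == 0:
        return np.empty(0, dtype=np.int64)
    key = variants.astype(np.int64) * (int(cleavages.max()) + 2) + cleavages
    order = np.lexsort((scores, key))
    _, first = np.unique(key[order], return_index=True)
    return order[first]


def _duplex_states(srna: str, target_window: str) -> List[str]:
    """Pairing states of an ungapped duplex, per sRNA position 5'->3'."""
    rc = _revcomp_codes(_encode(srna))
    t = _encode(target_window)
    states = []
    for p in range(1, len(srna) + 1):
        q = len(srna) - p
        pen = _PENALTY[rc[q], t[q]]
        states.append("match" if pen == 0.0 else ("gu" if pen == 0.5 else "mismatch"))
    return states


def predict_targets(
    srna_name: str,
    srna_seq: str,
    transcripts: Dict[str, str],
    max_score: float = 10.0,
) -> List[TargetSite]:
    """Predict target sites of one sRNA on a set of transcript sequences.

    One site is reported per (transcript, cleavage position), keeping the
    best-scoring duplex.  Pairing states are reconstructed for ungapped
    duplexes; bulged duplexes record the alignment shape only.
    """
    rc = _revcomp_codes(_encode(srna_seq))[None, :]
    m = len(srna_seq)
    sites: List[TargetSite] = []
    for tid in sorted(transcripts):
        tcodes = _encode(transcripts[tid])
        vv, oo, sc, cl, kind = _scan_batch(rc, tcodes, max_score)
        keep = _dedupe_by_site(vv, cl, sc)
        for i in keep:
            o = int(oo[i])
            states: List[str] = []
            if kind[i] == 0:
                states = _duplex_states(srna_seq, transcripts[tid][o : o + m])
            sites.append(
                TargetSite(
                    srna_name=srna_name,
                    transcript_id=tid,
                    start=o,
                    cleavage_offset=int(cl[i]),
                    allen_score=float(sc[i]),
                    states=states,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Site quantification
# ---------------------------------------------------------------------------

def _flank_max(dense: np.ndarray, window: int) -> np.ndarray:
    """Per-position maximum of counts over offsets within +-window, excluding
    the position itself and its two immediate neighbours; transcript bounds
    clip the window (an empty flank contributes 0)."""
    L = dense.size
    k = window - 1  # flank segment length on each side
    left_pad = np.concatenate([np.zeros(window), dense])
    left = sliding_window_view(left_pad, k)[:L].max(axis=1)
    right_pad = np.concatenate([dense, np.zeros(window + 2)])
    right = sliding_window_view(right_pad, k)[2 : L + 2].max(axis=1)
    return np.maximum(left, right)


def site_fold_change(track: TranscriptTrack, cleavage_offset: int, window: int = 50) -> float:
    """(reads at the site + 1) / (max reads in the flanking window + 1).

    Positions within 1 nt of the site are excluded from the flank so that
    slightly offset sRNA isoform sites do not penalize the call.
    """
    dense = track.dense()
    fm = _flank_max(dense, window)
    return float((dense[cleavage_offset] + 1.0) / (fm[cleavage_offset] + 1.0))


# ---------------------------------------------------------------------------
# Empirical null statistics
# ---------------------------------------------------------------------------

def empirical_pvalues(
    obs_fc: np.ndarray, obs_as: np.ndarray, null_fc: np.ndarray, null_as: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided add-one-corrected empirical p-values against pooled nulls.

    p_fc ranks the observed fold change against the null ECDF from above
    (large FC is extreme); p_as ranks the Allen score from below (low score
    is extreme).  With N null values, p = (1 + #{null at least as extreme})
    / (1 + N), so p is never zero and Fisher's method stays finite.
    """
    n = null_fc.size
    if n == 0 or null_as.size == 0:
        raise ValueError("empty null distribution")
    sfc = np.sort(null_fc)
    sas = np.sort(null_as)
    ge = n - np.searchsorted(sfc, np.asarray(obs_fc, dtype=float), side="left")
    le = np.searchsorted(sas, np.asarray(obs_as, dtype=float), side="right")
    p_fc = (1.0 + ge) / (1.0 + n)
    p_as = (1.0 + le) / (1.0 + null_as.size)
    return p_fc, p_as


def fisher_combine(p_fc: np.ndarray, p_as: np.ndarray) -> np.ndarray:
    """Fisher's combined probability: X = -2(ln p_fc + ln p_as) ~ chi2(4)."""
    x = -2.0 * (np.log(p_fc) + np.log(p_as))
    return sps.chi2.sf(x, df=4)


def rptm(site_reads: float, total_transcriptome_reads: float) -> float:
    """Reads per ten million transcriptome-mapping reads."""
    if total_transcriptome_reads <= 0:
        raise ValueError("total transcriptome reads must be > 0")
    return site_reads * 1e7 / total_transcriptome_reads


def combine_and_adjust(
    calls: pd.DataFrame,
    alpha: float = 0.05,
    min_fc: float = 1.0,
    min_rptm: float = 1.0,
    gate_window: int = 50,
) -> pd.DataFrame:
    """Add Fisher-combined and BH-adjusted p-values and the significance call.

    The BH family is every site tested in the library (all sRNAs pooled).
    """
    if len(calls) == 0:
        for col in ("p_combined", "p_adjusted"):
            calls[col] = pd.Series(dtype=float)
        calls["significant"] = pd.Series(dtype=bool)
        return calls
    calls = calls.copy()
    calls["p_combined"] = fisher_combine(calls["p_fc"].to_numpy(), calls["p_as"].to_numpy())
    calls["p_adjusted"] = multipletests(calls["p_combined"].to_numpy(), method="fdr_bh")[1]
    fc_col = f"fc{gate_window}"
    calls["significant"] = (
        (calls["p_adjusted"] < alpha)
        & (calls[fc_col] > min_fc)
        & (calls["rptm"] >= min_rptm)
    )
    return calls


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_endcut(
    srnas: Dict[str, str],
    transcript_seqs: Dict[str, str],
    tracks: Dict[str, TranscriptTrack],
    total_transcriptome_reads: float,
    n_shuffles: int = 1000,
    seed: int = 1,
    max_score: float = 10.0,
    gate_window: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full cleavage-site test for a set of sRNAs against one library.

    ``tracks`` maps transcript id to the cap-masked sense-strand 5P track of
    that transcript; transcripts without a track are skipped.  Returns one
    row per observed candidate site with both flanking windows (20 and 50
    nt), empirical p-values against the sRNA's shuffled cohort, and the final
    significance call (gated on ``gate_window``).
    """
    analyzed = sorted(set(transcript_seqs) & set(tracks))
    dense: Dict[str, np.ndarray] = {tid: tracks[tid].dense() for tid in analyzed}
    flank: Dict[int, Dict[str, np.ndarray]] = {
        w: {tid: _flank_max(dense[tid], w) for tid in analyzed} for w in (20, 50)
    }

    rows = []
    for idx, name in enumerate(sorted(srnas)):
        seq = srnas[name].upper().replace("U", "T")
        cohort = shuffle_srna(seq, n_shuffles, seed=(seed * 1000003 + idx) % (2**31))
        batch = np.stack([_encode(s) for s in [seq] + cohort])
        rc = _revcomp_codes(batch)

        null_fc: List[np.ndarray] = []
        null_as: List[np.ndarray] = []
        obs: List[Tuple[str, int, float]] = []
        for tid in analyzed:
            tcodes = _encode(transcript_seqs[tid])
            vv, oo, sc, cl, kind = _scan_batch(rc, tcodes, max_score)
            keep = _dedupe_by_site(vv, cl, sc)
            vv, sc, cl = vv[keep], sc[keep], cl[keep]
            d = dense[tid]
            fm = flank[gate_window][tid]
            fc_all = (d[cl] + 1.0) / (fm[cl] + 1.0)
            is_obs = vv == 0
            null_fc.append(fc_all[~is_obs])
            null_as.append(sc[~is_obs].astype(float))
            for c, s in zip(cl[is_obs], sc[is_obs]):
                obs.append((tid, int(c), float(s)))

        if not obs:
            continue
        nfc = np.concatenate(null_fc) if null_fc else np.empty(0)
        nas = np.concatenate(null_as) if null_as else np.empty(0)
        obs_fc = np.array([
            (dense[tid][c] + 1.0) / (flank[gate_window][tid][c] + 1.0) for tid, c, _ in obs
        ])
        obs_as = np.array([s for _, _, s in obs])
        p_fc, p_as = empirical_pvalues(obs_fc, obs_as, nfc, nas)
        for (tid, c, s), pf, pa, fc_gate in zip(obs, p_fc, p_as, obs_fc):
            site_reads = float(dense[tid][c])
            fc20 = (dense[tid][c] + 1.0) / (flank[20][tid][c] + 1.0)
            fc50 = (dense[tid][c] + 1.0) / (flank[50][tid][c] + 1.0)
            rows.append(
                {
                    "srna": name,
                    "transcript": tid,
                    "cleavage_offset": c,
                    "allen_score": s,
                    "site_reads": site_reads,
                    "fc20": float(fc20),
                    "fc50": float(fc50),
                    "p_fc": float(pf),
                    "p_as": float(pa),
                    "rptm": rptm(site_reads, total_transcriptome_reads),
                    "n_null": int(nfc.size),
                }
            )
    calls = pd.DataFrame(rows)
    return combine_and_adjust(calls, alpha=alpha, gate_window=gate_window)
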