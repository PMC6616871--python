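"""Scoring scan output against simulation truth: power, FPR, ROC, plot data.

Power for per-QTN truth is the fraction of replicates in which the QTN's
own p-value clears the threshold.  For the dense-QTL experiment a detected
SNP within 100 kb of a true QTL also counts: significant SNPs are greedily
matched (nearest first, each QTL and each SNP at most once) and power is
matched QTLs / total QTLs.  The false-positive denominator is the set of
tested SNPs that are neither true QTLs nor within the match window of one,
which makes null calibration testable (rate ~ alpha under the null).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EvaluationResult", "power_exact", "power_windowed",
           "false_positive_rate", "roc_curve", "qq_manhattan_data"]

DEFAULT_ALPHAS = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)


@dataclass
class EvaluationResult:
    per_qtn_power: list[float] = field(default_factory=list)
    overall_power: float | None = None
    false_positive_rate: float | None = None
    roc_points: list[dict] = field(default_factory=list)
    n_replicates: int = 0
    threshold: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pvalues(rep) -> np.ndarray:
    """Accept a DataFrame with a 'p' / 'p_value' column or a bare array."""
    if isinstance(rep, pd.DataFrame):
        col = "p" if "p" in rep.columns else "p_value"
        return rep[col].to_numpy(dtype=float)
    return np.asarray(rep, dtype=float)


def power_exact(replicates: Sequence, qtn_indices, threshold: float
                ) -> np.ndarray:
    """Per-QTN detection frequency at the QTN's exact marker index."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    hits = np.zeros(len(qtn_indices))
    for rep in replicates:
        p = _pvalues(rep)
        hits += (p[qtn_indices] < threshold).astype(float)
    return hits / len(replicates)


def _match_greedy(sig_idx: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                  qtl_idx: np.ndarray, match_bp: int
                  ) -> tuple[set[int], set[int]]:
    """Greedy nearest-first matching of significant SNPs to true QTLs.

    Returns (matched QTL indices, matched SNP indices); each QTL and each
    SNP participates in at most one match.
    """
    pairs = []
    for q in qtl_idx:
        same = sig_idx[chrom[sig_idx] == chrom[q]]
        d = np.abs(pos[same] - pos[q])
        for s, dist in zip(same[d <= match_bp], d[d <= match_bp]):
            pairs.append((dist, int(s), int(q)))
    pairs.sort()
    matched_q: set[int] = set()
    matched_s: set[int] = set()
    for _, s, q in pairs:
        if q in matched_q or s in matched_s:
            continue
        matched_q.add(q)
        matched_s.add(s)
    return matched_q, matched_s


def _window_info(rep: pd.DataFrame):
    for col in ("chrom", "pos"):
        if col not in rep.columns:
            raise ValueError("windowed evaluation needs 'chrom'/'pos' columns")
    return (rep["chrom"].to_numpy(), rep["pos"].to_numpy(dtype=np.int64))


def power_windowed(replicates, qtl_indices, threshold: float,
                   match_bp: int = 100_000):
    """Window-matched power: matched QTLs / total QTLs, averaged over replicates.

    Each replicate must be a result DataFrame in map order with 'chrom',
    'pos' and p-value columns.  Returns (overall_power, matched sets per
    replicate).
    """
    if isinstance(replicates, pd.DataFrame):
        replicates = [replicates]
    qtl_indices = np.asarray(qtl_indices, dtype=int)
    if len(qtl_indices) == 0:
        raise ValueError("no true QTLs in truth record")
    powers = []
    matches = []
    for rep in replicates:
        chrom, pos = _window_info(rep)
        p = _pvalues(rep)
        sig = np.flatnonzero(p < threshold)
        mq, ms = _match_greedy(sig, chrom, pos, qtl_indices, match_bp)
        powers.append(len(mq) / len(qtl_indices))
        matches.append((mq, ms))
    return float(np.mean(powers)), matches


def false_positive_rate(replicates, qtl_indices, threshold: float,
                        match_bp: int = 100_000) -> float:
    """Unmatched significant SNPs over SNPs eligible to be false positives.

    Eligible SNPs are those that are neither true QTLs nor within
    ``match_bp`` of one; the rate is averaged over replicates.
    """
    if isinstance(replicates, pd.DataFrame):
        replicates = [replicates]
    qtl_indices = np.asarray(qtl_indices, dtype=int)
    rates = []
    for rep in replicates:
        chrom, pos = _window_info(rep)
        p = _pvalues(rep)
        m = len(p)
        near = np.zeros(m, dtype=bool)
        for q in qtl_indices:
            near |= (chrom == chrom[q]) & (np.abs(pos - pos[q]) <= match_bp)
        denom = int((~near).sum())
        if denom == 0:
            raise ValueError("no SNPs eligible as false positives")
        sig = np.flatnonzero(p < threshold)
        mq, ms = _match_greedy(sig, chrom, pos, qtl_indices, match_bp) \
            if len(qtl_indices) else (set(), set())
        n_false = len(set(sig.tolist()) - ms)
        rates.append(n_false / denom)
    return float(np.mean(rates))


def roc_curve(replicates, qtl_indices,
              alphas: Sequence[float] = DEFAULT_ALPHAS) -> list[dict]:
    """(alpha, FPR, power) at fixed significance levels (windowed rules).

    With no true QTLs the power entries are None while FPR is still
    computed.
    """
    qtl_indices = np.asarray(qtl_indices, dtype=int)
    points = []
    for a in sorted(alphas):
        if len(qtl_indices):
            pw, _ = power_windowed(replicates, qtl_indices, a)
        else:
            pw = None
        fpr = false_positive_rate(replicates, qtl_indices, a)
        points.append({"alpha": float(a), "fpr": fpr, "power": pw})
    return points


def qq_manhattan_data(results: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables for Manhattan and QQ displays.

    Manhattan: cumulative genome coordinate (chromosomes laid end to end in
    order of appearance), -log10 p, chromosome block index.  QQ: expected
    -log10 uniform order statistics (i - 0.5)/m against observed sorted
    values.  NA records are dropped.
    """
    chrom, pos = _window_info(results)
    p = _pvalues(results)
    nl = results["neg_log10_p"].to_numpy(dtype=float) \
        if "neg_log10_p" in results.columns else -np.log10(p)
    ok = np.isfinite(p)

    blocks = pd.unique(chrom)
    offset = 0
    cum = np.zeros(len(p), dtype=np.int64)
    block_idx = np.zeros(len(p), dtype=np.int64)
    for bi, c in enumerate(blocks):
        sel = chrom == c
        cum[sel] = pos[sel] + offset
        block_idx[sel] = bi
        offset += int(pos[sel].max()) + 1
    manhattan = pd.DataFrame({
        "genome_bp": cum[ok], "neg_log10_p": nl[ok], "chrom_block": block_idx[ok],
    })

    obs = np.sort(nl[ok])[::-1]
    m = len(obs)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": expected, "observed": obs})
    return manhattan, qq
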