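"""Cohort-level utilities: junction-set matching, interchromosomal
restriction, binned junction density, and locus-conditioned differential
expression ("chromosomal DE plots").

The DE engine is self-contained: library-size normalization plus a
negative-binomial exact-style conditional test with tagwise dispersions
estimated by a moment/shrinkage scheme, reporting log2 fold changes and
Benjamini-Hochberg q-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom, pearsonr
from statsmodels.stats.multitest import multipletests

from .annotate import GeneModel, is_nonstandard_contig
from .model import JunctionCall


@dataclass
class MatchParams:
    window_nt: int = 40
    exclude_head_to_tail: bool = True
    exclude_alt_loci: bool = True
    interchromosomal_only: bool = False

    def __post_init__(self) -> None:
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")


@dataclass
class MatchResult:
    matched: list[tuple[JunctionCall, JunctionCall]]
    only_a: list[JunctionCall]
    only_b: list[JunctionCall]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _apply_exclusions(calls: Sequence[JunctionCall], params: MatchParams) -> list[JunctionCall]:
    out = []
    for c in calls:
        if params.exclude_head_to_tail and c.circ_flag:
            continue
        if params.exclude_alt_loci and (
            is_nonstandard_contig(c.breakendA.chrom) or is_nonstandard_contig(c.breakendB.chrom)
        ):
            continue
        if params.interchromosomal_only and not c.interchromosomal:
            continue
        out.append(c)
    return out


def _check_builds(a: Sequence[JunctionCall], b: Sequence[JunctionCall]) -> None:
    ca = {x.breakendA.chrom for x in a} | {x.breakendB.chrom for x in a}
    cb = {x.breakendA.chrom for x in b} | {x.breakendB.chrom for x in b}
    if ca and cb and not (ca & cb):
        raise ValueError(
            f"no shared contig names between the two junction sets "
            f"({sorted(ca)[:3]}... vs {sorted(cb)[:3]}...); mixed genome builds?"
        )


def match_junction_sets(
    a: Sequence[JunctionCall],
    b: Sequence[JunctionCall],
    params: Optional[MatchParams] = None,
) -> MatchResult:
    """Partition two junction sets into matched pairs and set-specific rests.

    Two junctions match when, after canonical ordering, both sides are on
    the same contig and within ``window_nt`` (boundary inclusive).
    Assignment is greedy by nearest pair; each junction matches at most
    once. Exclusions (head-to-tail, alternate loci, optionally
    intrachromosomal entries) are applied before matching.
    """
    params = params or MatchParams()
    _check_builds(a, b)
    fa = _apply_exclusions(a, params)
    fb = _apply_exclusions(b, params)
    w = params.window_nt
    candidates = []
    for i, x in enumerate(fa):
        for j, y in enumerate(fb):
            if x.breakendA.chrom != y.breakendA.chrom or x.breakendB.chrom != y.breakendB.chrom:
                continue
            dA = abs(x.breakendA.pos - y.breakendA.pos)
            dB = abs(x.breakendB.pos - y.breakendB.pos)
            if dA <= w and dB <= w:
                candidates.append((dA + dB, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((fa[i], fb[j]))
    only_a = [x for i, x in enumerate(fa) if i not in used_a]
    only_b = [y for j, y in enumerate(fb) if j not in used_b]
    return MatchResult(matched=matched, only_a=only_a, only_b=only_b)


def restrict_interchromosomal(calls: Iterable[JunctionCall]) -> list[JunctionCall]:
    """Keep only junctions whose two sides are on different chromosomes."""
    return [c for c in calls if c.interchromosomal]


def bin_junction_density(
    tracks: Mapping[str, Sequence[JunctionCall]],
    bin_size_nt: int,
    contig_lengths: Mapping[str, int],
    include_circ: bool = False,
) -> pd.DataFrame:
    """Per-bin endpoint counts, one column per track.

    Every junction contributes both endpoints to their bins; suspected
    circRNAs (head-to-tail flagged) are discarded unless requested.
    """
    index = []
    for chrom in sorted(contig_lengths):
        n_bins = int(np.ceil(contig_lengths[chrom] / bin_size_nt))
        index.extend((chrom, i * bin_size_nt) for i in range(max(n_bins, 1)))
    midx = pd.MultiIndex.from_tuples(index, names=["chrom", "bin_start"])
    df = pd.DataFrame(0, index=midx, columns=sorted(tracks), dtype=int)
    for name in df.columns:
        for c in tracks[name]:
            if c.circ_flag and not include_circ:
                continue
            for bk in (c.breakendA, c.breakendB):
                if bk.chrom in contig_lengths and bk.pos < contig_lengths[bk.chrom]:
                    df.loc[(bk.chrom, (bk.pos // bin_size_nt) * bin_size_nt), name] += 1
    return df


def track_correlation(density: pd.DataFrame, track_a: str, track_b: str) -> float:
    """Pearson correlation of two density tracks over matched bins."""
    x = density[track_a].to_numpy(dtype=float)
    y = density[track_b].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    return float(pearsonr(x, y)[0])


@dataclass
class LocusSplit:
    """Cohort split: mutant samples have >= 1 junction within the locus."""

    locus: tuple[str, int, int]  # 0-based half-open
    mutant_samples: set = field(default_factory=set)
    wildtype_samples: set = field(default_factory=set)


def split_cohort_by_locus(
    sample_junctions: Mapping[str, Sequence[JunctionCall]],
    locus: tuple[str, int, int],
    passing_only: bool = True,
) -> LocusSplit:
    """A sample is mutant iff it has >= 1 (passing) intronic or exonic
    junction with >= 1 breakend inside the locus."""
    chrom, start, end = locus
    split = LocusSplit(locus=locus)
    for sample, calls in sample_junctions.items():
        hit = False
        for c in calls:
            if passing_only and not c.passed:
                continue
            for bk in (c.breakendA, c.breakendB):
                if bk.chrom == chrom and start <= bk.pos < end:
                    hit = True
                    break
            if hit:
                break
        (split.mutant_samples if hit else split.wildtype_samples).add(sample)
    return split


# ---------------------------------------------------------------------------
# locus-conditioned differential expression


def _size_factors(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (robust to a minority of
    truly differential genes, unlike total-count scaling)."""
    pos = (mat > 0).all(axis=1)
    if pos.sum() >= 10:
        logs = np.log(mat[pos])
        ratios = logs - logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(ratios, axis=0))
    else:
        lib = mat.sum(axis=0)
        sf = lib / max(lib.mean(), 1.0)
    return np.where(sf > 0, sf, 1.0)


def _estimate_dispersions(z: np.ndarray, g1: np.ndarray, g2: np.ndarray, prior_df: float = 20.0) -> np.ndarray:
    """Tagwise NB dispersions by moments, shrunk toward the common value.

    z: normalized counts (genes x samples); g1/g2: boolean sample masks.
    """
    n1, n2 = int(g1.sum()), int(g2.sum())
    m1 = z[:, g1].mean(axis=1)
    m2 = z[:, g2].mean(axis=1)
    ss = ((z[:, g1] - m1[:, None]) ** 2).sum(axis=1) + ((z[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    v = ss / max(n1 + n2 - 2, 1)
    mu = (n1 * m1 + n2 * m2) / (n1 + n2)
    mu = np.maximum(mu, 1e-8)
    phi_raw = np.clip((v - mu) / mu**2, 1e-4, 5.0)
    common = float(np.median(phi_raw))
    df = n1 + n2 - 2
    return (df * phi_raw + prior_df * common) / (df + prior_df)


def _nb_exact_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Conditional exact-style two-sided p-value for NB group sums.

    The sum of n i.i.d. NB(mu, dispersion phi) counts is NB(n*mu, phi/n).
    Conditioning on the total, the p-value is the probability mass of all
    splits at most as likely as the observed one.
    """
    s = y1 + y2
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    r1, r2 = n1 / phi, n2 / phi
    p1 = r1 / (r1 + n1 * mu)
    p2 = r2 / (r2 + n2 * mu)
    k = np.arange(s + 1)
    logj = nbinom.logpmf(k, r1, p1) + nbinom.logpmf(s - k, r2, p2)
    logj -= logj.max()
    j = np.exp(logj)
    obs = j[y1]
    return float(j[j <= obs * (1 + 1e-10)].sum() / j.sum())


def chromosomal_de(
    counts: pd.DataFrame,
    split: LocusSplit,
    gene_models: Optional[Sequence[GeneModel]] = None,
    q_threshold: float = 0.05,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Mutant-vs-wildtype DE for every gene on the locus's chromosome.

    ``counts`` is a raw gene x sample matrix; library sizes are
    normalized internally. Returns a plot-ready table ordered by the
    gene's genomic center with log2 fold change (mutant vs wildtype),
    BH-adjusted q-values and an up/down/ns direction column.
    """
    mut = sorted(split.mutant_samples & set(counts.columns))
    wt = sorted(split.wildtype_samples & set(counts.columns))
    if len(mut) < 2 or len(wt) < 2:
        raise ValueError(
            f"both groups need >= 2 samples for DE (mutant={len(mut)}, wildtype={len(wt)})"
        )
    chrom = split.locus[0]
    centers: dict[str, float] = {}
    if gene_models is not None:
        keep = []
        for m in gene_models:
            if m.chrom == chrom:
                for key in (m.gene_id, m.gene_name):
                    centers[key] = m.center
                if m.gene_id in counts.index:
                    keep.append(m.gene_id)
                elif m.gene_name in counts.index:
                    keep.append(m.gene_name)
        counts = counts.loc[sorted(set(keep), key=keep.index)]
    if counts.empty:
        raise ValueError(f"no genes from the count matrix lie on {chrom}")

    cols = mut + wt
    mat = counts[cols].to_numpy(dtype=float)
    z = mat / _size_factors(mat)
    g1 = np.array([c in mut for c in cols])
    g2 = ~g1
    phi = _estimate_dispersions(z, g1, g2)
    m1 = z[:, g1].mean(axis=1)
    m2 = z[:, g2].mean(axis=1)
    logfc = np.log2((m1 + prior_count) / (m2 + prior_count))
    y1 = np.rint(z[:, g1].sum(axis=1)).astype(int)
    y2 = np.rint(z[:, g2].sum(axis=1)).astype(int)
    pvals = np.array(
        [
            _nb_exact_pvalue(int(a), int(b), int(g1.sum()), int(g2.sum()), float(f))
            for a, b, f in zip(y1, y2, phi)
        ]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    sig = qvals < q_threshold
    direction = np.where(~sig, "ns", np.where(logfc > 0, "up", "down"))
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "genomic_center": [centers.get(g, np.nan) for g in counts.index],
            "logFC": logfc,
            "p_value": pvals,
            "q_value": qvals,
            "significant": sig,
            "direction": direction,
        }
    )
    out = out.sort_values(["genomic_center", "gene"], na_position="last").reset_index(drop=True)
    return out
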