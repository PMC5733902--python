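"""Genotype filtering, 0/1/2 allele encoding, Bray-Curtis individual genetic
distances, PCA, and per-deme summary statistics (Fis, Weir-Cockerham Fst,
rarefied allelic richness)."""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_individuals(table: GenotypeTable, max_missing_loci: int = 2) -> GenotypeTable:
    """Remove individuals with strictly more than `max_missing_loci` missing
    loci. Individuals with exactly the threshold count are retained."""
    if max_missing_loci < 0:
        raise ValueError("max_missing_loci must be >= 0")
    n_missing = table.missing_mask().sum(axis=1)
    keep = n_missing <= max_missing_loci
    removed = int((~keep).sum())
    if removed:
        log.info("filter_individuals: removed %d of %d individuals", removed,
                 table.n_individuals)
    if not keep.any():
        warnings.warn("all individuals removed by missing-locus filter")
    ids = [iid for iid, k in zip(table.individual_id, keep) if k]
    return table.subset(ids)


def drop_loci(table: GenotypeTable, loci: Sequence[str]) -> GenotypeTable:
    """Remove the named loci from every record."""
    unknown = [l for l in loci if l not in table.loci]
    if unknown:
        raise ValueError(f"unknown loci: {unknown}")
    keep_idx = [j for j, l in enumerate(table.loci) if l not in set(loci)]
    return GenotypeTable(
        individual_id=list(table.individual_id),
        deme_id=list(table.deme_id),
        lon=table.lon.copy(),
        lat=table.lat.copy(),
        loci=[table.loci[j] for j in keep_idx],
        calls=table.calls[:, keep_idx, :].copy(),
        year=None if table.year is None else table.year.copy(),
        cluster_label=None if table.cluster_label is None else list(table.cluster_label),
    )


# ---------------------------------------------------------------------------
# Allele encoding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlleleMatrix:
    """Individuals x alleles 0/1/2 dosage matrix.

    `counts[i, a]` is the number of copies of allele column `a` carried by
    individual `i` (0 when absent, 1 for heterozygous, 2 for homozygous).
    Columns are grouped by locus, alleles sorted ascending within each locus.
    `missing[i, l]` masks loci untyped for an individual; the corresponding
    count entries are 0 and must be ignored through the mask.
    """

    counts: np.ndarray
    missing: np.ndarray
    columns: list[tuple[str, int]]
    loci: list[str]
    locus_slices: dict[str, slice]
    individual_id: list[str]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.counts.shape[1]

    def subset(self, ids: Sequence[str]) -> "AlleleMatrix":
        pos = {iid: k for k, iid in enumerate(self.individual_id)}
        idx = [pos[i] for i in ids]
        return AlleleMatrix(self.counts[idx], self.missing[idx], list(self.columns),
                            list(self.loci), dict(self.locus_slices), list(ids))


def encode_alleles(table: GenotypeTable) -> AlleleMatrix:
    """0/1/2 encoding: per allele column, 0 when absent, 1 when single at the
    locus (heterozygote) and 2 for homozygotes."""
    columns: list[tuple[str, int]] = []
    locus_slices: dict[str, slice] = {}
    allele_pos: dict[tuple[str, int], int] = {}
    for j, locus in enumerate(table.loci):
        observed = table.calls[:, j, :]
        alleles = sorted(int(a) for a in np.unique(observed) if a != MISSING)
        start = len(columns)
        for a in alleles:
            allele_pos[(locus, a)] = len(columns)
            columns.append((locus, a))
        locus_slices[locus] = slice(start, len(columns))
    n = table.n_individuals
    counts = np.zeros((n, len(columns)), dtype=np.int8)
    missing = table.missing_mask()
    for j, locus in enumerate(table.loci):
        for i in range(n):
            if missing[i, j]:
                continue
            a, b = int(table.calls[i, j, 0]), int(table.calls[i, j, 1])
            counts[i, allele_pos[(locus, a)]] += 1
            counts[i, allele_pos[(locus, b)]] += 1
    return AlleleMatrix(counts, missing, columns, list(table.loci), locus_slices,
                        list(table.individual_id))


# ---------------------------------------------------------------------------
# Bray-Curtis genetic distance
# ---------------------------------------------------------------------------

def bray_curtis(am: AlleleMatrix, on_no_shared: str = "error") -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity of 0/1/2 allele dosages.

    d(x, y) = 1 - 2 * sum_a min(x_a, y_a) / (sum_a x_a + sum_a y_a), computed
    over the loci typed in *both* individuals of each pair (pairwise
    deletion). Values lie in [0, 1].

    Parameters
    ----------
    on_no_shared : "error" or "nan" -- behaviour for pairs that share no
        typed locus.
    """
    if am.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    n = am.n_individuals
    typed = ~am.missing  # (n, L)
    # Per shared typed locus each individual contributes dosage total 2, so the
    # denominator is 4 * (#shared loci) and
    # sum_a min(x_a, y_a) = 2 - 0.5 * sum_a |x_a - y_a| per shared locus.
    shared = typed.astype(np.float64) @ typed.astype(np.float64).T  # (n, n)
    l1 = np.zeros((n, n))
    x = am.counts.astype(np.float64)
    for locus in am.loci:
        sl = am.locus_slices[locus]
        if sl.stop == sl.start:
            continue
        block = x[:, sl]
        # manhattan distance of this locus's columns; missing rows are all-0
        # and are neutralised by the shared-locus mask below
        d = np.abs(block[:, None, :] - block[None, :, :]).sum(axis=2)
        j = am.loci.index(locus)
        t = typed[:, j].astype(np.float64)
        l1 += d * np.outer(t, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = l1 / (4.0 * shared)
    np.fill_diagonal(dist, 0.0)
    no_shared = (shared == 0) & ~np.eye(n, dtype=bool)
    if no_shared.any():
        if on_no_shared == "error":
            raise ValueError("pair(s) share no typed locus")
        dist[no_shared] = np.nan
    return np.clip(dist, 0.0, 1.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(am: AlleleMatrix, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the allele dosage matrix.

    Masked (missing-locus) entries are imputed with the column mean over
    typed individuals; columns are centered but not scaled. Returns
    ``(scores, eigenvalues, percent_inertia)`` with eigenvalues defined on
    the 1/n covariance normalisation so that their sum equals the total
    variance of the centered matrix.
    """
    x = am.counts.astype(float).copy()
    for locus in am.loci:
        sl = am.locus_slices[locus]
        j = am.loci.index(locus)
        miss = am.missing[:, j]
        if miss.any():
            if miss.all():
                x[:, sl] = 0.0
                continue
            col_mean = x[~miss][:, sl].mean(axis=0)
            x[np.ix_(miss, range(sl.start, sl.stop))] = col_mean
    x -= x.mean(axis=0)
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / n
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_axes > rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {rank}; truncating")
        n_axes = rank
    scores = u[:, :n_axes] * s[:n_axes]
    total = eigvals.sum()
    percent = 100.0 * eigvals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return scores, eigvals[:n_axes], percent


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components_locus(calls_by_deme: list[np.ndarray]):
    """Weir-Cockerham (1984) variance components a, b, c summed over the
    alleles of one locus, for r >= 2 demes.

    `calls_by_deme[k]` is an (n_k, 2) integer array of allele calls, missing
    rows already removed. Returns (sum_a, sum_b, sum_c) over alleles.
    """
    r = len(calls_by_deme)
    sizes = np.array([c.shape[0] for c in calls_by_deme], dtype=float)
    if np.any(sizes < 1) or r < 2:
        return 0.0, 0.0, 0.0
    alleles = sorted(set(int(a) for c in calls_by_deme for a in c.reshape(-1)))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    nbar = sizes.mean()
    nc = (r * nbar - (sizes ** 2).sum() / (r * nbar)) / (r - 1)
    if nbar <= 1 or nc <= 0:
        return 0.0, 0.0, 0.0
    sum_a = sum_b = sum_c = 0.0
    for allele in alleles:
        p = np.array([np.mean(c == allele) for c in calls_by_deme])
        # frequency of heterozygotes carrying this allele
        h = np.array([np.mean((c[:, 0] == allele) != (c[:, 1] == allele))
                      for c in calls_by_deme])
        pbar = (sizes * p).sum() / (r * nbar)
        s2 = (sizes * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (sizes * h).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a, sum_b, sum_c


def _deme_calls(table: GenotypeTable, deme: str, locus_idx: int) -> np.ndarray:
    rows = [i for i, d in enumerate(table.deme_id) if d == deme]
    calls = table.calls[rows, locus_idx, :]
    keep = ~np.all(calls == MISSING, axis=1)
    return calls[keep]


def fst_wc(table: GenotypeTable, deme_a: str, deme_b: str) -> float:
    """Multilocus Weir-Cockerham theta between two demes.

    theta = sum(a) / sum(a + b + c), summed over alleles and loci.
    Returns NaN when every locus is monomorphic across the pair.
    """
    for d in (deme_a, deme_b):
        if table.deme_id.count(d) < 2:
            raise ValueError(f"deme {d!r} needs n >= 2")
    num = den = 0.0
    for j in range(table.n_loci):
        group = [_deme_calls(table, deme_a, j), _deme_calls(table, deme_b, j)]
        if any(g.shape[0] < 1 for g in group):
            continue
        a, b, c = _wc_components_locus(group)
        num += a
        den += a + b + c
    if den == 0.0:
        return float("nan")
    return num / den


def fis(table: GenotypeTable, group: Sequence[str] | None = None) -> float:
    """Multilocus Weir-Cockerham small-f within one group of individuals.

    f = 1 - sum(c) / sum(b + c) with the single-population variance
    components b (between individuals) and c (within individuals).
    `group` is a list of individual ids; None means the whole table.
    """
    if group is None:
        ids = list(table.individual_id)
    else:
        ids = list(group)
    sub = table.subset(ids)
    if sub.n_individuals < 2:
        raise ValueError("group needs n >= 2")
    sum_b = sum_c = 0.0
    poly = False
    for j in range(sub.n_loci):
        calls = sub.calls[:, j, :]
        keep = ~np.all(calls == MISSING, axis=1)
        calls = calls[keep]
        n = calls.shape[0]
        if n < 2:
            continue
        alleles = sorted(set(int(a) for a in calls.reshape(-1)))
        if len(alleles) < 2:
            continue
        poly = True
        for allele in alleles:
            p = np.mean(calls == allele)
            hbar = np.mean((calls[:, 0] == allele) != (calls[:, 1] == allele))
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
            c = hbar / 2.0
            sum_b += b
            sum_c += c
    if not poly or (sum_b + sum_c) == 0.0:
        return float("nan")
    return 1.0 - sum_c / (sum_b + sum_c)


def fis_per_deme(table: GenotypeTable) -> pd.Series:
    out = {}
    for deme in sorted(set(table.deme_id)):
        ids = [i for i, d in zip(table.individual_id, table.deme_id) if d == deme]
        out[deme] = fis(table, ids) if len(ids) >= 2 else float("nan")
    return pd.Series(out, name="Fis")


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(table: GenotypeTable, deme: str, g: int) -> float:
    """Expected number of distinct alleles in a subsample of `g` gene copies,
    averaged over loci: per locus sum_a [1 - C(N - N_a, g) / C(N, g)].

    Loci with fewer than `g` typed gene copies are skipped with a warning.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    per_locus = []
    for j in range(table.n_loci):
        calls = _deme_calls(table, deme, j)
        gene_copies = calls.reshape(-1)
        big_n = gene_copies.size
        if big_n < g:
            warnings.warn(f"locus {table.loci[j]!r}: only {big_n} gene copies "
                          f"in deme {deme!r}, < g={g}; skipped")
            continue
        values, counts = np.unique(gene_copies, return_counts=True)
        rest = big_n - counts
        term = np.where(rest >= g,
                        np.exp(_log_comb(rest.astype(float), g)
                               - _log_comb(float(big_n), g)),
                        0.0)
        per_locus.append(float(np.sum(1.0 - term)))
    if not per_locus:
        return float("nan")
    return float(np.mean(per_locus))


def default_rarefaction_g(table: GenotypeTable) -> int:
    """2 x smallest deme size among demes with n >= 2."""
    counts = pd.Series(table.deme_id).value_counts()
    counts = counts[counts >= 2]
    if counts.empty:
        raise ValueError("no deme with n >= 2")
    return int(2 * counts.min())


def deme_summaries(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Per-deme n, mean alleles per locus (A), rarefied richness (AR) and Fis."""
    if g is None:
        g = default_rarefaction_g(table)
    rows = []
    for deme in sorted(set(table.deme_id)):
        ids = [i for i, d in zip(table.individual_id, table.deme_id) if d == deme]
        n = len(ids)
        a_counts = []
        for j in range(table.n_loci):
            calls = _deme_calls(table, deme, j)
            if calls.size:
                a_counts.append(len(np.unique(calls.reshape(-1))))
        mean_a = float(np.mean(a_counts)) if a_counts else float("nan")
        ar = rarefied_richness(table, deme, g) if n >= 1 else float("nan")
        f = fis(table, ids) if n >= 2 else float("nan")
        rows.append({"deme_id": deme, "n": n, "A": mean_a, "AR": ar, "Fis": f})
    return pd.DataFrame(rows)
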