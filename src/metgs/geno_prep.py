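"""SNP marker preprocessing for inbred-line genomic selection.

Raw biallelic calls on (nominally homozygous) inbred lines are coded
0 = homozygous minor allele, 2 = homozygous major allele, 1 = heterozygous,
NaN = missing.  Heterozygous calls in an inbred population indicate calling
errors and are set to missing.  The cleaning pipeline then

1. drops markers that are monomorphic among non-missing calls, or carry
   more than ``max_missing_frac`` missing calls, or have minor allele
   frequency ≤ ``maf_min`` (strict ">" retained);
2. imputes the remaining missing calls by iterated k-nearest-neighbour
   averaging over lines, snapping imputed values to {0, 2} when within
   ``tol``, and discards markers that fail to converge to a homozygous
   code;
3. re-applies the polymorphism/MAF filter (imputation shifts allele
   counts) and removes exact duplicate marker columns, keeping the first
   by input order.

The result is the complete {0, 2} matrix ``M`` (lines × markers) consumed
by the RR-BLUP models, plus a report of what was removed and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawGenotypes",
    "MarkerMatrix",
    "recode_heterozygotes",
    "filter_markers",
    "impute_missing",
    "deduplicate_markers",
    "preprocess",
]


@dataclass
class RawGenotypes:
    """Lines × markers call matrix over {0, 1, 2, NaN}."""

    calls: np.ndarray
    line_ids: list
    marker_ids: list

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match identifier lists")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line identifiers")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker identifiers")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes present: {bad}")

    def select_markers(self, keep: np.ndarray) -> "RawGenotypes":
        keep = np.asarray(keep)
        return RawGenotypes(
            self.calls[:, keep],
            list(self.line_ids),
            [self.marker_ids[j] for j in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.marker_ids[j] for j in keep],
        )


@dataclass
class MarkerMatrix:
    """Complete {0, 2} genotype matrix M (v lines × p markers)."""

    M: np.ndarray
    line_ids: list
    marker_ids: list

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("M shape does not match identifier lists")
        if np.isnan(self.M).any():
            raise ValueError("MarkerMatrix must be complete (no missing entries)")
        if not np.isin(self.M, (0.0, 2.0)).all():
            raise ValueError("MarkerMatrix entries must be in {0, 2}")

    @property
    def v(self) -> int:
        return self.M.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]

    def relationship(self) -> np.ndarray:
        """Realized genomic relationship matrix K = M Mᵀ (unscaled)."""
        return self.M @ self.M.T

    def select_lines(self, line_ids) -> "MarkerMatrix":
        lut = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in lut]
        if missing:
            raise KeyError(f"lines without genotypes: {missing[:5]}")
        idx = [lut[l] for l in line_ids]
        return MarkerMatrix(self.M[idx], list(line_ids), list(self.marker_ids))


def _maf(col: np.ndarray) -> float:
    """Minor allele frequency of a {0,2}-coded column (NaN ignored)."""
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return 0.0
    f0 = float(np.mean(obs == 0.0))
    return min(f0, 1.0 - f0)


def recode_heterozygotes(raw: RawGenotypes) -> tuple[RawGenotypes, int]:
    """Replace heterozygous calls (code 1) by missing; returns the count."""
    calls = raw.calls.copy()
    het = calls == 1.0
    calls[het] = np.nan
    return (
        RawGenotypes(calls, list(raw.line_ids), list(raw.marker_ids)),
        int(het.sum()),
    )


def filter_markers(
    raw: RawGenotypes, max_missing_frac: float = 0.2, maf_min: float = 0.05
) -> tuple[RawGenotypes, dict]:
    """Drop monomorphic, too-missing, and low-MAF markers.

    Polymorphism and MAF are judged on non-missing calls only; the MAF rule
    is strict (markers with MAF exactly ``maf_min`` are removed).
    """
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    calls = raw.calls
    v = calls.shape[0]
    removed = {"missing": [], "monomorphic": [], "maf": []}
    keep = np.ones(calls.shape[1], dtype=bool)
    for j in range(calls.shape[1]):
        col = calls[:, j]
        miss = float(np.isnan(col).mean())
        if miss > max_missing_frac:
            removed["missing"].append(raw.marker_ids[j])
            keep[j] = False
            continue
        maf = _maf(col)
        if maf == 0.0:
            removed["monomorphic"].append(raw.marker_ids[j])
            keep[j] = False
        elif maf <= maf_min:
            removed["maf"].append(raw.marker_ids[j])
            keep[j] = False
    if not keep.any():
        raise ValueError("no markers survive filtering")
    return raw.select_markers(keep), removed


def impute_missing(
    raw: RawGenotypes,
    k_neighbors: int = 10,
    max_iter: int = 5,
    tol: float = 0.4,
) -> tuple[MarkerMatrix, list]:
    """Fill missing calls by iterated k-nearest-neighbour averaging.

    Line-to-line distances are root-mean-square differences over markers
    observed in both lines (computed once on the observed data).  At each
    round every originally-missing cell is re-estimated as the mean of the
    current values of the ``k_neighbors`` nearest lines with information at
    that marker, then snapped to 0 or 2 when within ``tol``.  Markers still
    carrying a non-{0,2} value after ``max_iter`` rounds are discarded and
    reported.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be at least 1")
    calls = raw.calls
    v, p = calls.shape
    missing = np.isnan(calls)
    if not missing.any():
        return MarkerMatrix(calls.copy(), list(raw.line_ids), list(raw.marker_ids)), []

    obs = ~missing
    # pairwise RMS distance on shared observed markers
    dist = np.zeros((v, v))
    for i in range(v):
        shared = obs[i] & obs
        diff = np.where(shared, calls[i] - np.nan_to_num(calls), 0.0)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.sqrt((diff**2).sum(axis=1) / cnt)
        dist[i, cnt == 0] = np.inf
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1)  # nearest lines first, per line

    cur = calls.copy()
    cur[missing] = np.nan
    for _ in range(max_iter):
        new = cur.copy()
        for i in range(v):
            cols = np.flatnonzero(missing[i])
            if cols.size == 0:
                continue
            for j in cols:
                have = ~np.isnan(cur[:, j])
                have[i] = False
                nbrs = [q for q in order[i] if have[q]][:k_neighbors]
                if not nbrs:
                    continue
                val = float(np.mean(cur[nbrs, j]))
                if abs(val - 0.0) <= tol:
                    val = 0.0
                elif abs(val - 2.0) <= tol:
                    val = 2.0
                new[i, j] = val
        cur = new
        filled = ~np.isnan(cur)
        if filled.all() and np.isin(cur, (0.0, 2.0)).all():
            break

    ok = np.array(
        [np.isin(cur[:, j], (0.0, 2.0)).all() and not np.isnan(cur[:, j]).any()
         for j in range(p)]
    )
    discarded = [raw.marker_ids[j] for j in np.flatnonzero(~ok)]
    if not ok.any():
        raise ValueError("no markers survive imputation")
    mm = MarkerMatrix(
        cur[:, ok],
        list(raw.line_ids),
        [raw.marker_ids[j] for j in np.flatnonzero(ok)],
    )
    return mm, discarded


def deduplicate_markers(m: MarkerMatrix) -> tuple[MarkerMatrix, dict]:
    """Remove exact duplicate columns; first occurrence (input order) wins."""
    seen: dict[bytes, int] = {}
    groups: dict[str, list] = {}
    keep = []
    for j in range(m.p):
        key = m.M[:, j].tobytes()
        if key in seen:
            groups.setdefault(m.marker_ids[seen[key]], []).append(m.marker_ids[j])
        else:
            seen[key] = j
            keep.append(j)
    mm = MarkerMatrix(m.M[:, keep], list(m.line_ids), [m.marker_ids[j] for j in keep])
    return mm, groups


def preprocess(
    raw: RawGenotypes,
    max_missing_frac: float = 0.2,
    maf_min: float = 0.05,
    k_neighbors: int = 10,
    max_iter: int = 5,
    tol: float = 0.4,
) -> tuple[MarkerMatrix, dict]:
    """Full cleaning pipeline: recode → filter → impute → re-filter → dedup.

    Returns the final marker matrix and a report dict (counts per rule).
    The pipeline is idempotent: running it on its own output is a no-op.
    """
    raw, n_het = recode_heterozygotes(raw)
    raw, removed_pre = filter_markers(raw, max_missing_frac, maf_min)
    mm, discarded = impute_missing(raw, k_neighbors, max_iter, tol)
    # imputation can shift allele counts: re-apply polymorphism/MAF rules
    post = RawGenotypes(mm.M, list(mm.line_ids), list(mm.marker_ids))
    post, removed_post = filter_markers(post, max_missing_frac, maf_min)
    mm = MarkerMatrix(post.calls, list(post.line_ids), list(post.marker_ids))
    mm, dup_groups = deduplicate_markers(mm)
    report = {
        "heterozygotes_recoded": n_het,
        "removed_missing": len(removed_pre["missing"]),
        "removed_monomorphic": len(removed_pre["monomorphic"])
        + len(removed_post["monomorphic"]),
        "removed_maf": len(removed_pre["maf"]) + len(removed_post["maf"]),
        "discarded_imputation": len(discarded),
        "duplicates_removed": sum(len(g) for g in dup_groups.values()),
        "duplicate_groups": dup_groups,
        "markers_kept": mm.p,
    }
    return mm, report
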