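"""Differentially methylated region discovery from CpG beta matrices.

The discovery cascade, stage by stage:

1. **DML calling** — a locus is differentially methylated iff the two-sample
   t-test between case and control betas gives p < .01 AND the absolute
   group-mean difference exceeds .1.
2. **Merging** — DML within 100 bp on the same chromosome merge into initial
   DMRs.
3. **Seed testing** — each initial DMR's per-sample mean beta (over its CpGs)
   is re-tested; regions with p < .01 become seed DMRs.
4. **CBS segmentation** — the per-locus case-control beta difference track is
   segmented by circular binary segmentation: recursively find the arc (i, j]
   maximizing the two-sample t-statistic between inside and outside loci, and
   accept the split when its permutation p-value beats alpha.
5. **Segment clustering** — k-means on segment mean differences; clusters
   with at least one segment fully containing a seed DMR are selected, and
   every segment of a selected cluster becomes a true DMR candidate.
6. **Accessibility filtering** — candidates must overlap (>= 1 bp) an
   epithelial accessibility peak.
7. **Core selection** — candidate mean betas are Z-normalized, samples are
   Ward-clustered, each candidate's hyper-methylation state (sample mean
   beta above the per-candidate median) is tested against the pathology
   label by Fisher's exact test; BH-adjusted p < .05 retains a core DMR.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from ._stats import rowwise_ttest
from .evaluation import benjamini_hochberg, fisher_exact

__all__ = [
    "call_dml",
    "merge_dml",
    "test_seed_dmr",
    "cbs_segment",
    "cluster_segments",
    "filter_by_peaks",
    "select_core_dmr",
    "DMRDiscovery",
]


def _split_groups(beta: pd.DataFrame, labels: pd.Series):
    samples = [c for c in beta.columns if c not in ("chrom", "pos")]
    lab = labels.reindex(samples)
    groups = lab.dropna().unique().tolist()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    case, control = sorted(groups)  # 'case' < 'control' lexically; order only flips delta sign
    case_cols = [s for s in samples if lab[s] == case]
    ctrl_cols = [s for s in samples if lab[s] == control]
    return case_cols, ctrl_cols


def call_dml(beta: pd.DataFrame, labels: pd.Series, p_thresh: float = 0.01,
             delta_thresh: float = 0.1, equal_var: bool = False,
             max_missing: float = 0.5) -> pd.DataFrame:
    """Call differentially methylated loci.

    ``beta`` has columns chrom, pos plus one column per sample; ``labels``
    maps samples to the two groups ("case" is the lexically smaller label).
    Loci missing in more than ``max_missing`` of either group are skipped.

    Returns the full per-locus table with columns chrom, pos, pvalue, delta,
    is_dml (p < p_thresh AND |delta| > delta_thresh, both strict).
    """
    case_cols, ctrl_cols = _split_groups(beta, labels)
    xc = beta[case_cols].to_numpy(dtype=float)
    x0 = beta[ctrl_cols].to_numpy(dtype=float)
    p, delta = rowwise_ttest(xc, x0, equal_var=equal_var)
    frac_c = np.isnan(xc).mean(axis=1)
    frac_0 = np.isnan(x0).mean(axis=1)
    usable = (frac_c <= max_missing) & (frac_0 <= max_missing)
    out = beta[["chrom", "pos"]].copy()
    out["pvalue"] = np.where(usable, p, np.nan)
    out["delta"] = delta
    out["is_dml"] = usable & (out["pvalue"] < p_thresh) & \
        (np.abs(out["delta"]) > delta_thresh)
    return out


def merge_dml(dml: pd.DataFrame, max_gap: int = 100) -> pd.DataFrame:
    """Merge DML within ``max_gap`` bp (same chrom) into initial DMR intervals.

    Input needs columns chrom, pos (DML loci only, sorted); singleton loci
    become width-1 intervals [pos, pos+1).
    """
    if len(dml) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpg"])
    rows = []
    for chrom, grp in dml.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        start = prev = pos[0]
        n = 1
        for p in pos[1:]:
            if p - prev <= max_gap:
                prev = p
                n += 1
            else:
                rows.append({"chrom": chrom, "start": int(start),
                             "end": int(prev) + 1, "n_cpg": n})
                start = prev = p
                n = 1
        rows.append({"chrom": chrom, "start": int(start), "end": int(prev) + 1,
                     "n_cpg": n})
    return pd.DataFrame(rows)


def _region_mean_beta(beta: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Per-region per-sample mean beta (regions x samples)."""
    samples = [c for c in beta.columns if c not in ("chrom", "pos")]
    rows = []
    for r in regions.itertuples():
        mask = (beta["chrom"] == r.chrom) & (beta["pos"] >= r.start) & (beta["pos"] < r.end)
        rows.append(beta.loc[mask, samples].mean(axis=0, skipna=True))
    return pd.DataFrame(rows, index=regions.index)


def test_seed_dmr(initial: pd.DataFrame, beta: pd.DataFrame, labels: pd.Series,
                  p_thresh: float = 0.01, equal_var: bool = False) -> pd.DataFrame:
    """Keep initial DMRs whose region-mean beta separates the groups (p < .01,
    strict)."""
    if len(initial) == 0:
        return initial.assign(pvalue=pd.Series(dtype=float))
    case_cols, ctrl_cols = _split_groups(beta, labels)
    means = _region_mean_beta(beta, initial)
    p, _ = rowwise_ttest(means[case_cols].to_numpy(), means[ctrl_cols].to_numpy(),
                         equal_var=equal_var)
    out = initial.copy()
    out["pvalue"] = p
    return out[out["pvalue"] < p_thresh].reset_index(drop=True)


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_t(x: np.ndarray, min_arc: int = 2):
    """Max two-sample |t| over all arcs (i, j], inside vs outside.

    Returns (tmax, i, j).  Arcs keep at least ``min_arc`` points on each side.
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n + 1)
    # widths w = j - i, need min_arc <= w <= n - min_arc
    sums = S[None, :] - S[:, None]          # sums[i, j] = sum x[i:j]
    sqs = Q[None, :] - Q[:, None]
    w = i[None, :] - i[:, None]
    valid = (w >= min_arc) & (w <= n - min_arc)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_f = w.astype(float)
        out_w = n - w_f
        mean_in = sums / w_f
        mean_out = (S[-1] - sums) / out_w
        ss_in = sqs - w_f * mean_in**2
        ss_out = (Q[-1] - sqs) - out_w * mean_out**2
        sp2 = (ss_in + ss_out) / (n - 2)
        t = (mean_in - mean_out) / np.sqrt(sp2 * (1 / w_f + 1 / out_w))
    t = np.where(valid, np.abs(t), -np.inf)
    flat = np.nanargmax(np.where(np.isnan(t), -np.inf, t))
    bi, bj = np.unravel_index(flat, t.shape)
    return t[bi, bj], int(bi), int(bj)


def _perm_pvalue(x: np.ndarray, t_obs: float, n_perm: int,
                 rng: np.random.Generator, min_arc: int = 2,
                 chunk: int = 50) -> float:
    """Permutation p-value of the max-arc statistic (position permutation)."""
    count = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        for _ in range(b):
            xp = rng.permutation(x)
            t_p, _, _ = _max_arc_t(xp, min_arc)
            if t_p >= t_obs:
                count += 1
        done += b
        # early exit once significance is impossible at any common alpha
        if count > 0.2 * n_perm:
            return (count + 1) / (done + 1)
    return (count + 1) / (n_perm + 1)


def cbs_segment(delta: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                seed: int | None = None, min_width: int = 4,
                min_arc: int = 2) -> pd.DataFrame:
    """Circular binary segmentation of a per-locus difference track.

    Recursively finds the arc (i, j] with maximal inside-vs-outside pooled
    t-statistic and accepts the split when its permutation p-value (within
    the current segment) is below ``alpha``.  Segments shorter than
    ``min_width`` are never split.

    Returns a DataFrame with columns start, end (half-open locus indices),
    mean (segment mean delta), n.  The segments partition [0, len(delta)).
    """
    if seed is None:
        raise ValueError("cbs_segment requires an explicit seed")
    x = np.asarray(delta, dtype=float)
    rng = np.random.default_rng(seed)
    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        n = len(seg)
        if n < min_width or np.ptp(seg) == 0:
            boundaries.append((lo, hi))
            return
        t_obs, i, j = _max_arc_t(seg, min_arc)
        if not np.isfinite(t_obs):
            boundaries.append((lo, hi))
            return
        p = _perm_pvalue(seg, t_obs, n_perm, rng, min_arc)
        if p >= alpha:
            boundaries.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        pieces = zip([0] + cuts, cuts + [n])
        for a, b in pieces:
            if a < b:
                recurse(lo + a, lo + b)

    recurse(0, len(x))
    boundaries.sort()
    return pd.DataFrame(
        [{"start": a, "end": b, "mean": float(x[a:b].mean()), "n": b - a}
         for a, b in boundaries]
    )


def cluster_segments(segments: pd.DataFrame, seeds: pd.DataFrame, k: int = 3,
                     seed: int | None = None) -> pd.DataFrame:
    """k-means on segment mean deltas; select clusters whose segments fully
    encompass at least one seed DMR.

    ``segments`` needs genomic columns chrom, start, end plus ``mean``;
    ``seeds`` are seed DMR intervals.  Returns the segments of selected
    clusters (the true DMR candidates) with their cluster id.
    """
    if k > len(segments):
        raise ValueError(f"k={k} exceeds the number of segments ({len(segments)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    seg = segments.copy().reset_index(drop=True)
    seg["cluster"] = km.fit_predict(seg[["mean"]].to_numpy())
    contains_seed = np.zeros(len(seg), dtype=bool)
    for s in seeds.itertuples():
        contains_seed |= (
            (seg["chrom"] == s.chrom) & (seg["start"] <= s.start) & (seg["end"] >= s.end)
        ).to_numpy()
    selected = seg.loc[contains_seed, "cluster"].unique()
    return seg[seg["cluster"].isin(selected)].reset_index(drop=True)


def filter_by_peaks(candidates: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Keep candidates overlapping (>= 1 bp) any accessibility peak."""
    if len(candidates) == 0 or len(peaks) == 0:
        return candidates.iloc[0:0]
    keep = np.zeros(len(candidates), dtype=bool)
    for i, c in enumerate(candidates.itertuples()):
        on_chrom = peaks[peaks["chrom"] == c.chrom]
        keep[i] = bool(((on_chrom["start"] < c.end) & (on_chrom["end"] > c.start)).any())
    return candidates[keep].reset_index(drop=True)


def select_core_dmr(candidates: pd.DataFrame, beta: pd.DataFrame,
                    pathology: pd.Series, n_groups: int = 2,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Select core DMRs by association of hyper-methylation with pathology.

    Per-candidate sample mean betas are Z-normalized and the samples
    Ward-clustered into ``n_groups`` (the unsupervised grouping is reported
    as ``sample_clusters_`` on the returned frame's attrs).  Each candidate's
    hyper-methylation state (mean beta above the per-candidate median) is
    tested against the pathology label with Fisher's exact test; candidates
    with BH-adjusted p < alpha are retained.
    """
    classes = pathology.dropna().unique()
    if len(classes) < 2:
        raise ValueError("pathology labels must contain at least two classes")
    if len(candidates) == 0:
        return candidates.assign(pvalue=pd.Series(dtype=float),
                                 p_adj=pd.Series(dtype=float))
    means = _region_mean_beta(beta, candidates)
    labelled = [c for c in means.columns if pd.notna(pathology.get(c))]
    means = means[labelled]
    sd = means.std(axis=1, ddof=0).replace(0, np.nan)
    z = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    link = linkage(z.T.to_numpy(), method="ward")
    sample_clusters = pd.Series(fcluster(link, t=n_groups, criterion="maxclust"),
                                index=means.columns, name="cluster")
    lab = pathology.reindex(means.columns)
    is_first = (lab == classes[0]).to_numpy()
    pvals = np.ones(len(candidates))
    for i in range(len(candidates)):
        vals = means.iloc[i].to_numpy(dtype=float)
        if np.all(np.isnan(vals)) or np.nanstd(vals) == 0:
            pvals[i] = 1.0
            continue
        hyper = vals > np.nanmedian(vals)
        a = int(np.sum(hyper & is_first))
        b = int(np.sum(hyper & ~is_first))
        c = int(np.sum(~hyper & is_first))
        d = int(np.sum(~hyper & ~is_first))
        pvals[i] = fisher_exact([[a, b], [c, d]]).pvalue
    out = candidates.copy()
    out["pvalue"] = pvals
    out["p_adj"] = benjamini_hochberg(pvals)
    core = out[out["p_adj"] < alpha].reset_index(drop=True)
    core.attrs["sample_clusters"] = sample_clusters
    return core


class DMRDiscovery(BaseEstimator):
    """End-to-end DMR discovery estimator.

    fit(beta, labels, pathology=None, peaks=None) runs the full cascade and
    exposes every stage:  ``dml_``, ``initial_dmrs_``, ``seed_dmrs_``,
    ``segments_``, ``candidates_``, ``filtered_candidates_``, ``core_dmrs_``.

    Parameters mirror the stage functions; ``random_state`` seeds both CBS
    permutations and k-means.
    """

    def __init__(self, p_thresh: float = 0.01, delta_thresh: float = 0.1,
                 max_gap: int = 100, seed_p_thresh: float = 0.01,
                 alpha: float = 0.01, n_perm: int = 1000, k: int = 3,
                 n_groups: int = 2, core_alpha: float = 0.05,
                 equal_var: bool = False, random_state: int = 0):
        self.p_thresh = p_thresh
        self.delta_thresh = delta_thresh
        self.max_gap = max_gap
        self.seed_p_thresh = seed_p_thresh
        self.alpha = alpha
        self.n_perm = n_perm
        self.k = k
        self.n_groups = n_groups
        self.core_alpha = core_alpha
        self.equal_var = equal_var
        self.random_state = random_state

    def fit(self, beta: pd.DataFrame, labels: pd.Series,
            pathology: pd.Series | None = None,
            peaks: pd.DataFrame | None = None):
        self.dml_ = call_dml(beta, labels, self.p_thresh, self.delta_thresh,
                             self.equal_var)
        dml_loci = self.dml_[self.dml_["is_dml"]]
        self.initial_dmrs_ = merge_dml(dml_loci, self.max_gap)
        self.seed_dmrs_ = test_seed_dmr(self.initial_dmrs_, beta, labels,
                                        self.seed_p_thresh, self.equal_var)
        case_cols, ctrl_cols = _split_groups(beta, labels)
        segs = []
        for chrom, grp in beta.groupby("chrom", sort=False):
            delta = (grp[case_cols].mean(axis=1, skipna=True)
                     - grp[ctrl_cols].mean(axis=1, skipna=True)).to_numpy()
            s = cbs_segment(delta, self.alpha, self.n_perm, self.random_state)
            pos = grp["pos"].to_numpy()
            s["chrom"] = chrom
            s["start"] = pos[s["start"].to_numpy()]
            s["end"] = pos[s["end"].to_numpy() - 1] + 1
            segs.append(s)
        self.segments_ = pd.concat(segs, ignore_index=True)[
            ["chrom", "start", "end", "mean", "n"]]
        self.candidates_ = cluster_segments(self.segments_, self.seed_dmrs_,
                                            self.k, self.random_state)
        if peaks is not None:
            self.filtered_candidates_ = filter_by_peaks(self.candidates_, peaks)
        else:
            self.filtered_candidates_ = self.candidates_
        if pathology is not None:
            self.core_dmrs_ = select_core_dmr(self.filtered_candidates_, beta,
                                              pathology, self.n_groups,
                                              self.core_alpha)
        else:
            self.core_dmrs_ = None
        return self
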