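"""Synthetic bisulfite-amplicon and WGBS-like data with known ground truth.

The generator emulates the three reference tissue classes of a urine-based
bladder-cancer methylation assay — low-grade (LG) tumour, high-grade (HG)
tumour and normal urine — at the level of per-amplicon methylation-haplotype
distributions.  A haplotype is the per-read methylation frequency rounded to
one decimal, so every distribution lives on the 11 bins {0.0, 0.1, ..., 1.0}.

Structure of the emulated assay:

* T1 ("passenger") amplicons carry one dominant haplotype per class; both
  tumour classes share the same tumour haplotype, which differs from the
  urine haplotype.  Haplotype diversity is low in every class.
* T2 ("driver") amplicons carry tumour-specific haplotypes (TSH) with exactly
  zero prevalence in normal urine; the HG class spreads its mass over several
  TSH bins, giving it strictly higher haplotype entropy than LG or urine.
  ``entropy_contrast`` scales both the class shift and the number of HG TSH
  bins; at 0 all three classes collapse onto the urine profile (no signal).

Tumour-into-urine mixtures are exact convex combinations of profiles, so a
serial dilution series has known truth at every fraction.  Replicates of one
dilution are technical replicates: reads are multinomial draws from the same
mixture profile.  Cohort donors additionally receive Dirichlet dispersion
around their class profile.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import round_half_up

__all__ = [
    "BINS",
    "SimulationConfig",
    "TissueClassProfile",
    "SimulatedCohort",
    "make_reference_profiles",
    "simulate_mixture",
    "simulate_haplotype_counts",
    "simulate_reads",
    "build_reference",
    "simulate_dilution_series",
    "simulate_cohort",
    "simulate_beta_matrix",
    "PAPER_DILUTION_FRACTIONS",
]

#: the 11 rounded methylation-frequency bins a haplotype can take
BINS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.05, 0.1), 1))

#: serial-dilution design: 100%, 20%, 10%, 5%, 2.5%, 1%, .5% and .1% mix-in
PAPER_DILUTION_FRACTIONS: tuple[float, ...] = (
    1.0, 0.20, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic assay.

    coverage is reads per amplicon per sample; conversion_failure_rate is the
    per-non-CpG-cytosine probability of escaping bisulfite conversion;
    entropy_contrast scales the tumour-vs-urine signal and the extra HG
    haplotype diversity on driver amplicons (2 = full contrast).
    """

    n_amplicons: int = 20
    n_t1dmr: int = 10
    n_t2dmr: int = 10
    # 10 CpGs is the smallest count for which every rounded-frequency bin
    # 0.0..1.0 is expressible as an integer methylated-CpG ratio
    cpg_per_amplicon: int = 10
    coverage: int = 2000
    conversion_failure_rate: float = 0.003
    low_mapq_fraction: float = 0.02
    seed: int = 0
    dilution_fractions: tuple[float, ...] = PAPER_DILUTION_FRACTIONS
    replicates_per_fraction: int = 5
    entropy_contrast: float = 2.0
    amplicon_length: int = 120
    noncpg_c_per_amplicon: int = 10
    donor_concentration: float = 300.0

    def __post_init__(self):
        if self.n_t1dmr + self.n_t2dmr != self.n_amplicons:
            raise ValueError(
                f"n_t1dmr ({self.n_t1dmr}) + n_t2dmr ({self.n_t2dmr}) "
                f"must equal n_amplicons ({self.n_amplicons})"
            )
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not all(0.0 <= f <= 1.0 for f in self.dilution_fractions):
            raise ValueError("dilution fractions must lie in [0, 1]")
        if not 0.0 <= self.conversion_failure_rate <= 1.0:
            raise ValueError("conversion_failure_rate must lie in [0, 1]")
        if self.entropy_contrast < 0:
            raise ValueError("entropy_contrast must be >= 0")
        if self.cpg_per_amplicon < 1:
            raise ValueError("cpg_per_amplicon must be >= 1")

    def amplicon_names(self) -> list[str]:
        return [f"amp{i:03d}" for i in range(self.n_amplicons)]

    def dmr_types(self) -> pd.Series:
        """True DMR type per amplicon: first n_t1dmr are T1, rest T2."""
        types = ["T1"] * self.n_t1dmr + ["T2"] * self.n_t2dmr
        return pd.Series(types, index=self.amplicon_names(), name="dmr_type")


@dataclass
class TissueClassProfile:
    """Per-amplicon haplotype-bin probability vectors for one tissue class."""

    class_label: str
    probs: pd.DataFrame  # index: amplicon names, columns: BINS, rows sum to 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        cols = [round(float(c), 1) for c in self.probs.columns]
        if cols != [round(b, 1) for b in BINS]:
            raise ValueError("profile columns must be the 11 haplotype bins 0.0..1.0")
        row_sums = self.probs.to_numpy().sum(axis=1)
        if np.any(self.probs.to_numpy() < -1e-12) or np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("each per-amplicon probability vector must sum to 1")

    @property
    def amplicons(self) -> list[str]:
        return list(self.probs.index)

    def entropy(self) -> pd.Series:
        """Shannon entropy (nats) of each amplicon's haplotype distribution."""
        p = self.probs.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        return pd.Series(h, index=self.probs.index, name="entropy")


@dataclass
class SimulatedCohort:
    """A fully simulated set of samples with complete ground truth."""

    haplotype_table: pd.DataFrame      # sample, amplicon, bin, count, prevalence
    truth: pd.DataFrame                # per sample: class label, tumour fraction
    amplicon_types: pd.Series          # per amplicon: true DMR type (T1/T2)
    profiles: dict = field(default_factory=dict)


def _bin_index(b: float) -> int:
    return int(round(b * 10))


def _amplicon_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-amplicon bin assignments (home/tumour/LG/HG bins)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    names = config.amplicon_names()
    types = config.dmr_types()
    rows = []
    n_hg_bins = max(2, 2 + int(round(config.entropy_contrast)))
    for name in names:
        home = float(rng.choice([0.0, 0.1]))
        lg_bin = 0.5
        hg_pool = [b for b in (0.4, 0.6, 0.7, 0.8, 0.9, 1.0)
                   if b not in (home, round(home + 0.1, 1), lg_bin)]
        hg_bins = sorted(rng.choice(hg_pool, size=min(n_hg_bins, len(hg_pool)),
                                    replace=False).tolist())
        rows.append({"amplicon": name, "dmr_type": types[name], "home": home,
                     "lg_bin": lg_bin, "hg_bins": tuple(hg_bins)})
    return pd.DataFrame(rows).set_index("amplicon")


def make_reference_profiles(config: SimulationConfig):
    """Build the (LG, HG, URINE) reference haplotype profiles.

    Returns a dict {"LG": ..., "HG": ..., "URINE": ...} of TissueClassProfile.
    The class shift away from the urine background scales with
    ``entropy_contrast`` (s = contrast/2, clipped to [0, 1]); at contrast 0
    the three profiles are identical and carry no signal.
    """
    layout = _amplicon_layout(config)
    s = float(np.clip(config.entropy_contrast / 2.0, 0.0, 1.0))
    n_bins = len(BINS)
    urine = np.zeros((config.n_amplicons, n_bins))
    lg = np.zeros_like(urine)
    hg = np.zeros_like(urine)
    for i, (name, row) in enumerate(layout.iterrows()):
        h = _bin_index(row["home"])
        base = np.zeros(n_bins)
        base[h] = 0.9
        base[h + 1] = 0.1
        urine[i] = base
        if row["dmr_type"] == "T1":
            target = np.zeros(n_bins)
            target[_bin_index(1.0)] = 0.85
            target[_bin_index(0.9)] = 0.15
            lg_target = hg_target = target
        else:
            lg_target = np.zeros(n_bins)
            lg_target[_bin_index(row["lg_bin"])] = 0.7
            lg_target[h] = 0.3
            hg_target = np.zeros(n_bins)
            hg_bins = row["hg_bins"]
            hg_target[[_bin_index(b) for b in hg_bins]] = 0.9 / len(hg_bins)
            hg_target[h] = 0.1
        lg[i] = (1 - s) * base + s * lg_target
        hg[i] = (1 - s) * base + s * hg_target
    idx = pd.Index(layout.index, name="amplicon")
    cols = list(BINS)
    return {
        "LG": TissueClassProfile("LG", pd.DataFrame(lg, index=idx, columns=cols)),
        "HG": TissueClassProfile("HG", pd.DataFrame(hg, index=idx, columns=cols)),
        "URINE": TissueClassProfile("URINE", pd.DataFrame(urine, index=idx, columns=cols)),
    }


def simulate_mixture(tumor: TissueClassProfile, urine: TissueClassProfile,
                     fraction: float) -> TissueClassProfile:
    """Convex combination fraction*tumor + (1-fraction)*urine, per amplicon."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if list(tumor.probs.index) != list(urine.probs.index):
        raise ValueError("profiles are defined on different amplicon sets")
    probs = fraction * tumor.probs + (1.0 - fraction) * urine.probs
    label = f"mix_{tumor.class_label}_{fraction:g}"
    return TissueClassProfile(label, probs)


def perturb_profile(profile: TissueClassProfile, rng: np.random.Generator,
                    concentration: float) -> TissueClassProfile:
    """Donor-level dispersion: Dirichlet(concentration * p) on the support.

    Bins with exactly zero probability stay exactly zero, preserving the
    absence of tumour-specific haplotypes from normal urine.
    """
    probs = profile.probs.to_numpy().copy()
    for i in range(probs.shape[0]):
        support = probs[i] > 0
        if support.sum() > 1:
            probs[i, support] = rng.dirichlet(concentration * probs[i, support])
    return TissueClassProfile(
        profile.class_label, pd.DataFrame(probs, index=profile.probs.index,
                                          columns=profile.probs.columns)
    )


def simulate_haplotype_counts(profile: TissueClassProfile, coverage: int,
                              rng: np.random.Generator, sample_id: str) -> pd.DataFrame:
    """Multinomial haplotype counts at the given coverage, long format.

    Output columns: sample, amplicon, bin, count, prevalence — the same
    layout the read-level extraction stage produces.
    """
    p = profile.probs.to_numpy()
    rows = []
    for i, amp in enumerate(profile.probs.index):
        counts = rng.multinomial(coverage, p[i] / p[i].sum())
        for j, b in enumerate(BINS):
            if counts[j] > 0:
                rows.append((sample_id, amp, b, int(counts[j]), counts[j] / coverage))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "bin", "count", "prevalence"])


# ---------------------------------------------------------------------------
# read-level simulation (SAM + reference FASTA)
# ---------------------------------------------------------------------------

def build_reference(config: SimulationConfig):
    """Synthetic reference: one contig per amplicon.

    Each contig carries ``cpg_per_amplicon`` CpG sites and
    ``noncpg_c_per_amplicon`` isolated non-CpG cytosines at deterministic
    positions, embedded in an A/T background.

    Returns (sequences, amplicons): dict contig -> sequence, and a DataFrame
    with columns chrom/start/end/name plus per-amplicon CpG and non-CpG-C
    positions (0-based).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    L = config.amplicon_length
    n_cpg = config.cpg_per_amplicon
    n_c = config.noncpg_c_per_amplicon
    n_sites = n_cpg + n_c
    if 3 * n_sites + 2 >= L:
        raise ValueError("amplicon_length too short for the requested site counts")
    seqs: dict[str, str] = {}
    rows = []
    for name in config.amplicon_names():
        bases = rng.choice(list("AT"), size=L).tolist()
        # evenly spaced candidate site positions, leaving room for the CG dinucleotide
        sites = np.linspace(2, L - 3, n_sites).astype(int)
        order = rng.permutation(n_sites)
        cpg_pos = sorted(int(sites[k]) for k in order[:n_cpg])
        c_pos = sorted(int(sites[k]) for k in order[n_cpg:])
        for p in cpg_pos:
            bases[p] = "C"
            bases[p + 1] = "G"
        for p in c_pos:
            bases[p] = "C"
            bases[p + 1] = "A" if bases[p + 1] == "G" else bases[p + 1]
        seqs[name] = "".join(bases)
        rows.append({"chrom": name, "start": 0, "end": L, "name": name,
                     "cpg_positions": tuple(cpg_pos), "noncpg_c_positions": tuple(c_pos)})
    return seqs, pd.DataFrame(rows)


def _methylated_count_for_bin(b: float, n_cpg: int, rng: np.random.Generator) -> int:
    """Sample an integer methylated-CpG count whose ratio rounds to bin b."""
    valid = [m for m in range(n_cpg + 1) if round_half_up(m / n_cpg) == round(b, 1)]
    if not valid:
        # no integer ratio rounds to this bin at this CpG count; take nearest
        m = int(np.clip(round(b * n_cpg), 0, n_cpg))
        return m
    return int(rng.choice(valid))


def simulate_reads(profile: TissueClassProfile, config: SimulationConfig,
                   sample_id: str, reference=None):
    """Simulate aligned bisulfite reads for one sample.

    Each read spans its amplicon contig; its CpG pattern is drawn so the
    rounded methylation frequency equals a haplotype bin sampled from the
    profile.  Non-CpG cytosines escape conversion with probability
    ``conversion_failure_rate``; ``low_mapq_fraction`` of reads get MAPQ 20
    (rest 60).  Deterministic given config.seed and sample_id.

    Returns (records, sequences, amplicons) where records is a list of dicts
    ready to be written as SAM lines.
    """
    if reference is None:
        reference = build_reference(config)
    seqs, amplicons = reference
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 303, zlib.crc32(sample_id.encode())])
    )
    amp_info = amplicons.set_index("name")
    records = []
    bins = np.array(BINS)
    for amp in profile.probs.index:
        p = profile.probs.loc[amp].to_numpy()
        cpg_pos = list(amp_info.loc[amp, "cpg_positions"])
        c_pos = list(amp_info.loc[amp, "noncpg_c_positions"])
        ref = seqs[amp]
        drawn = rng.choice(len(bins), size=config.coverage, p=p / p.sum())
        for r in range(config.coverage):
            b = float(bins[drawn[r]])
            m = _methylated_count_for_bin(b, len(cpg_pos), rng)
            meth_sites = set(rng.choice(len(cpg_pos), size=m, replace=False).tolist())
            read = list(ref)
            for k, pos in enumerate(cpg_pos):
                read[pos] = "C" if k in meth_sites else "T"
            for pos in c_pos:
                if rng.random() >= config.conversion_failure_rate:
                    read[pos] = "T"
            mapq = 20 if rng.random() < config.low_mapq_fraction else 60
            records.append({
                "qname": f"{sample_id}:{amp}:{r}",
                "rname": amp,
                "pos": 0,
                "mapq": mapq,
                "cigar": f"{len(ref)}M",
                "seq": "".join(read),
            })
    return records, seqs, amplicons


def write_sam(records, seqs, path) -> None:
    """Write simulated alignment records as a plain-text SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in seqs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            fh.write(
                f"{rec['qname']}\t0\t{rec['rname']}\t{rec['pos'] + 1}\t{rec['mapq']}\t"
                f"{rec['cigar']}\t*\t0\t0\t{rec['seq']}\t*\n"
            )


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_amplicon_bed(amplicons: pd.DataFrame, path) -> None:
    amplicons[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_dilution_series(config: SimulationConfig, tumor_class: str = "HG",
                             include_blank: bool = True) -> SimulatedCohort:
    """Serial dilution of a tumour profile into normal urine.

    ``replicates_per_fraction`` technical replicates per fraction (multinomial
    sampling from the same mixture profile at the configured coverage), plus
    blank (0%) samples unless a 0 fraction is already listed.
    """
    if not config.dilution_fractions:
        raise ValueError("dilution_fractions must be non-empty")
    profiles = make_reference_profiles(config)
    tumor = profiles[tumor_class]
    urine = profiles["URINE"]
    fractions = list(config.dilution_fractions)
    if include_blank and 0.0 not in fractions:
        fractions.append(0.0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    tables, truth_rows = [], []
    for f in fractions:
        mix = simulate_mixture(tumor, urine, f)
        for r in range(config.replicates_per_fraction):
            sid = f"dil_{f:g}_{r}"
            tables.append(simulate_haplotype_counts(mix, config.coverage, rng, sid))
            truth_rows.append({"sample": sid, "class": tumor_class if f > 0 else "URINE",
                               "fraction": f})
    return SimulatedCohort(
        haplotype_table=pd.concat(tables, ignore_index=True),
        truth=pd.DataFrame(truth_rows).set_index("sample"),
        amplicon_types=config.dmr_types(),
        profiles=profiles,
    )


def simulate_cohort(config: SimulationConfig, n_hg: int, n_lg: int, n_urine: int,
                    dispersion: bool = True,
                    donor_seed: int | None = None) -> SimulatedCohort:
    """A labelled cohort of HG / LG tumour tissues and normal urines.

    Each donor draws a Dirichlet-perturbed copy of its class profile
    (concentration ``donor_concentration``), then multinomial haplotype counts
    at the configured coverage.  ``donor_seed`` draws a fresh set of donors on
    the same reference profiles (config.seed), e.g. for held-out cohorts.
    """
    profiles = make_reference_profiles(config)
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed if donor_seed is None else donor_seed, 505]))
    tables, truth_rows = [], []
    for label, n in (("HG", n_hg), ("LG", n_lg), ("URINE", n_urine)):
        for i in range(n):
            sid = f"{label.lower()}_{i:02d}"
            prof = profiles[label]
            if dispersion:
                prof = perturb_profile(prof, rng, config.donor_concentration)
            tables.append(simulate_haplotype_counts(prof, config.coverage, rng, sid))
            truth_rows.append({"sample": sid, "class": label,
                               "fraction": 1.0 if label != "URINE" else 0.0})
    return SimulatedCohort(
        haplotype_table=pd.concat(tables, ignore_index=True),
        truth=pd.DataFrame(truth_rows).set_index("sample"),
        amplicon_types=config.dmr_types(),
        profiles=profiles,
    )


# ---------------------------------------------------------------------------
# WGBS-like beta matrices with planted DMRs
# ---------------------------------------------------------------------------

def simulate_beta_matrix(n_per_group: int, n_cpg: int, planted_dmrs,
                         effect: float, seed: int, noise_sd: float = 0.08,
                         peak_fraction: float = 1.0, decoy_peaks: int = 1,
                         chrom: str = "chr1"):
    """CpG-by-sample beta matrix with planted case-hypermethylated DMRs.

    Parameters
    ----------
    planted_dmrs : list of (start_locus, end_locus)
        Disjoint half-open locus-index ranges to receive the effect.
    effect : float in (0, 1] (0 allowed for null simulations)
        Mean beta shift added to the case group inside planted DMRs.
    peak_fraction : float
        Fraction of planted DMRs covered by an accessibility peak; one decoy
        peak outside every planted region is always added.

    Returns
    -------
    (beta, labels, truth_intervals, peaks):
        beta — DataFrame with columns chrom, pos and one column per sample;
        labels — Series sample -> 'case'/'control';
        truth_intervals / peaks — BED-like DataFrames (chrom, start, end).
    """
    if effect < 0 or effect > 1:
        raise ValueError("effect must lie in [0, 1]")
    ivals = sorted(tuple(v) for v in planted_dmrs)
    for (a0, a1), (b0, b1) in zip(ivals[:-1], ivals[1:]):
        if b0 < a1:
            raise ValueError("planted DMR intervals must be disjoint")
    for a0, a1 in ivals:
        if not (0 <= a0 < a1 <= n_cpg):
            raise ValueError("planted DMR locus range outside the matrix")
    rng = np.random.default_rng(seed)
    gaps = rng.integers(30, 151, size=n_cpg)
    pos = 1000 + np.cumsum(gaps)
    base = rng.uniform(0.2, 0.6, size=n_cpg)
    in_dmr = np.zeros(n_cpg, dtype=bool)
    for a0, a1 in ivals:
        in_dmr[a0:a1] = True
    samples = [f"case_{i:02d}" for i in range(n_per_group)] + \
              [f"ctrl_{i:02d}" for i in range(n_per_group)]
    labels = pd.Series(["case"] * n_per_group + ["control"] * n_per_group,
                       index=samples, name="group")
    betas = rng.normal(base[:, None], noise_sd, size=(n_cpg, 2 * n_per_group))
    betas[in_dmr, :n_per_group] += effect
    betas = np.clip(betas, 0.0, 1.0)
    beta = pd.DataFrame(betas, columns=samples)
    beta.insert(0, "pos", pos)
    beta.insert(0, "chrom", chrom)
    truth = pd.DataFrame(
        [{"chrom": chrom, "start": int(pos[a0]), "end": int(pos[a1 - 1]) + 1}
         for a0, a1 in ivals]
    )
    peak_rows = []
    n_covered = int(round(peak_fraction * len(ivals)))
    for j, (a0, a1) in enumerate(ivals):
        if j < n_covered:
            peak_rows.append({"chrom": chrom,
                              "start": max(0, int(pos[a0]) - 50),
                              "end": int(pos[a1 - 1]) + 51})
    # decoy peak in a region without planted signal
    free = np.flatnonzero(~in_dmr)
    if free.size and decoy_peaks > 0:
        mid = int(free[len(free) // 2])
        peak_rows.append({"chrom": chrom, "start": int(pos[mid]), "end": int(pos[mid]) + 200})
    peaks = pd.DataFrame(peak_rows)
    return beta, labels, truth, peaks
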