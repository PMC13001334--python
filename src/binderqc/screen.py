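"""Pooled-screen quantification and CD20-specific enrichment calling.

The screen compares barcode abundance of each designed binder between a
target co-culture condition (cd20pos) and a no-target control (cd20neg),
three replicates each, with the design's own coding sequence acting as the
barcode. The statistical machinery follows the standard small-replicate
count-data playbook:

- counts are modeled negative-binomially with mean mu and variance
  mu(1 + phi*mu) (phi = dispersion);
- a common dispersion is estimated by method-of-moments across designs and
  optionally shrunk toward per-design (tagwise) estimates;
- significance comes from an exact conditional test: after equalizing
  library sizes, the within-condition sums are NB-distributed, and the
  p-value is the double-tail probability of splits of the pooled total at
  least as extreme as observed (binomial-conditional in the Poisson limit);
- Benjamini-Hochberg FDR is applied over recovered designs only, since
  designs under the read-recovery threshold are excluded from analysis.

A design is a hit ("enriched") when it is recovered, FDR < 0.05 and
logFC >= 1 (at least twofold CD20-specific enrichment); symmetric for
"depleted".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

MIN_READS_DEFAULT = 25
FDR_THRESHOLD = 0.05
LOGFC_THRESHOLD = 1.0


@dataclass
class CountMatrix:
    """Design x replicate integer read counts with condition labels.

    ``conditions`` maps each column to one of {"cd20pos", "cd20neg",
    "input"}. Column sums act as library sizes.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        """Infer conditions from column names (input, cd20pos_*, cd20neg_*)."""
        conditions = {}
        for col in df.columns:
            if col == "input":
                conditions[col] = "input"
            elif col.startswith("cd20pos"):
                conditions[col] = "cd20pos"
            elif col.startswith("cd20neg"):
                conditions[col] = "cd20neg"
            else:
                raise ValueError(f"cannot infer condition for column {col!r}")
        return cls(df, conditions)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate design ids: {dups[:5]}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        for cond in ("cd20pos", "cd20neg"):
            if not self.replicates(cond):
                raise ValueError(f"no replicate columns for condition {cond!r}")

    def replicates(self, condition: str) -> list[str]:
        return [c for c, cond in self.conditions.items() if cond == condition]

    @property
    def design_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_columns(self) -> list[str]:
        """The six screen replicates (input excluded)."""
        return self.replicates("cd20pos") + self.replicates("cd20neg")


def count_barcodes(
    fastq_path: str | Path,
    library: dict[str, str],
    offset: int = 0,
    max_mismatches: int = 0,
) -> tuple[pd.Series, int]:
    """Assign reads to designs by exact match of the design-length substring.

    Each design's codon-optimized coding sequence is its own barcode. Reads
    are matched at ``offset``; with ``max_mismatches=1`` a Hamming-1 rescue
    pass runs over the library (linear scan; intended for small libraries).
    Duplicate library sequences are collapsed to the first id with a warning.
    Returns (per-design counts, number of unassigned reads).
    """
    import gzip

    from Bio import SeqIO

    if not library:
        raise ValueError("empty barcode library")
    seq_to_id: dict[str, str] = {}
    for design_id, seq in library.items():
        if seq in seq_to_id:
            warnings.warn(
                f"duplicate library sequence: {design_id} collapsed into {seq_to_id[seq]}"
            )
            continue
        seq_to_id[seq] = design_id
    lengths = sorted({len(s) for s in seq_to_id})

    counts = {design_id: 0 for design_id in library}
    unassigned = 0
    opener = gzip.open if str(fastq_path).endswith(".gz") else open
    handle = opener(str(fastq_path), "rt")
    for rec in SeqIO.parse(handle, "fastq"):
        read = str(rec.seq)
        hit = None
        for L in lengths:
            sub = read[offset : offset + L]
            if sub in seq_to_id:
                hit = seq_to_id[sub]
                break
        if hit is None and max_mismatches >= 1:
            for L in lengths:
                sub = read[offset : offset + L]
                if len(sub) != L:
                    continue
                for seq, design_id in seq_to_id.items():
                    if len(seq) == L and sum(a != b for a, b in zip(sub, seq)) <= max_mismatches:
                        hit = design_id
                        break
                if hit:
                    break
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    handle.close()
    return pd.Series(counts, name="count"), unassigned


def classify_recovery(cm: CountMatrix, min_reads: int = MIN_READS_DEFAULT) -> pd.Series:
    """Recovered <=> count >= min_reads in every screen replicate (input excluded).

    Failing this threshold is read as the CAR not sustaining T-cell fitness
    (or never being expressed), so such designs leave the analysis entirely.
    """
    cols = cm.condition_columns()
    return (cm.counts[cols] >= min_reads).all(axis=1)


def normalize_cpm(
    cm: CountMatrix,
    use_tmm: bool = False,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million per column; optionally TMM-adjusted library sizes.

    ``library_sizes`` overrides the column sums (e.g. to hold sizes equal
    when studying the raw-count behavior of the fold-change estimate).
    """
    lib = (library_sizes if library_sizes is not None else cm.library_sizes).astype(float)
    if (lib == 0).any():
        zero = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size in column(s) {zero}")
    if use_tmm:
        lib = lib * tmm_factors(cm.counts)
    return cm.counts.div(lib, axis=1) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (product = 1).

    The reference column is the one whose upper quartile is closest to the
    mean upper quartile. Proportional columns yield factors of exactly 1.
    """
    lib = counts.sum(axis=0).astype(float)
    uq = counts[counts > 0].quantile(0.75) / lib
    ref = (uq - uq.mean()).abs().idxmin()
    y_r = counts[ref].to_numpy(float)
    n_r = lib[ref]
    log_factors = {}
    for col in counts.columns:
        if col == ref:
            log_factors[col] = 0.0
            continue
        y_k = counts[col].to_numpy(float)
        n_k = lib[col]
        keep = (y_k > 0) & (y_r > 0)
        yk, yr = y_k[keep], y_r[keep]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        w = 1.0 / ((n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep2 = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep2.any():
            log_factors[col] = 0.0
        else:
            log_factors[col] = float(np.average(m[keep2], weights=w[keep2]))
    f = pd.Series(log_factors).reindex(counts.columns)
    f = f - f.mean()  # geometric mean of factors = 1
    return np.exp2(f)


def _equalized_counts(cm: CountMatrix) -> tuple[pd.DataFrame, float]:
    """Scale screen-replicate counts to a common (geometric-mean) library size."""
    cols = cm.condition_columns()
    lib = cm.library_sizes[cols].astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    common = float(np.exp(np.log(lib).mean()))
    eq = cm.counts[cols].astype(float).mul(common / lib, axis=1)
    return eq, common


def estimate_dispersion(
    cm: CountMatrix,
    recovered: pd.Series | None = None,
    tagwise_weight: float = 0.2,
    min_mean: float = 1.0,
) -> pd.Series:
    """Method-of-moments NB dispersion, moderated toward the common value.

    For each design and condition with >=2 replicates, phi_hat = (s^2-m)/m^2
    on library-size-equalized counts, clipped at 0 and averaged over
    conditions. The common dispersion is the mean tagwise estimate over
    designs with mean count >= min_mean; each design's final dispersion is
    (1-w)*common + w*tagwise. w=0 gives a pure common dispersion.
    """
    eq, _ = _equalized_counts(cm)
    per_design = []
    for cond in ("cd20pos", "cd20neg"):
        cols = cm.replicates(cond)
        if len(cols) < 2:
            continue
        sub = eq[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = ((v - m) / m**2).where(m > 0)
        per_design.append(phi.clip(lower=0.0))
    if not per_design:
        raise ValueError("need >=2 replicates in at least one condition")
    tagwise = pd.concat(per_design, axis=1).mean(axis=1)

    mask = eq.mean(axis=1) >= min_mean
    if recovered is not None:
        mask &= recovered.reindex(tagwise.index, fill_value=False)
    common = float(tagwise[mask].mean()) if mask.any() else float(tagwise.mean())
    common = max(common, 1e-8)
    out = (1.0 - tagwise_weight) * common + tagwise_weight * tagwise.fillna(common)
    return out.clip(lower=1e-8)


def nb_exact_test(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float,
) -> float:
    """Exact conditional two-sided p-value for a two-group NB comparison.

    ``sum_a``/``sum_b`` are within-group count sums over ``n_a``/``n_b``
    replicates at equalized library sizes. Conditional on the pooled total
    s, the split follows the ratio of NB pmfs (group sums are NB with size
    n/phi); the p-value sums the probabilities of all splits no more likely
    than the observed one (double tail). As phi -> 0 this reduces to the
    binomial-conditional (exact Poisson ratio) test.
    """
    sum_a, sum_b = int(round(sum_a)), int(round(sum_b))
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if dispersion < 1e-12:
        probs = binom.pmf(y, s, n_a / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)  # per-replicate mean under the null
        q = 1.0 / (1.0 + dispersion * mu)
        logp = nbinom.logpmf(y, n_a / dispersion, q) + nbinom.logpmf(
            s - y, n_b / dispersion, q
        )
        logp -= logsumexp(logp)
        probs = np.exp(logp)
    # Relative tie tolerance: outcomes whose pmf ties the observed one must
    # count toward the tail even when tiny dispersion perturbs exact
    # (rational) binomial ties; perturbation scale is ~ phi * s^2.
    p_obs = probs[sum_a]
    p = float(probs[probs <= p_obs * (1.0 + 1e-4)].sum())
    return min(1.0, p)


def test_enrichment(
    cm: CountMatrix,
    min_reads: int = MIN_READS_DEFAULT,
    pseudocount_cpm: float = 0.5,
    dispersion: float | pd.Series | None = None,
    tagwise_weight: float = 0.2,
    use_tmm: bool = False,
    library_sizes: pd.Series | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    logfc_threshold: float = LOGFC_THRESHOLD,
) -> pd.DataFrame:
    """Per-design CD20-specific enrichment calls.

    Returns a DataFrame indexed by design_id with columns: recovered, logFC,
    p_value, fdr, category, rank_score. logFC is
    log2((mean CPM cd20pos + c) / (mean CPM cd20neg + c)); p-values come from
    :func:`nb_exact_test` at the (estimated or supplied) dispersion; BH FDR
    runs over recovered designs only, and non-recovered designs carry no
    p/fdr and category "not_recovered". rank_score = -log10(fdr) * logFC.
    """
    recovered = classify_recovery(cm, min_reads=min_reads)
    cpm = normalize_cpm(cm, use_tmm=use_tmm, library_sizes=library_sizes)
    pos_cols = cm.replicates("cd20pos")
    neg_cols = cm.replicates("cd20neg")
    mean_pos = cpm[pos_cols].mean(axis=1)
    mean_neg = cpm[neg_cols].mean(axis=1)
    c = pseudocount_cpm
    logfc = np.log2((mean_pos + c) / (mean_neg + c))

    if dispersion is None:
        phi = estimate_dispersion(cm, recovered=recovered, tagwise_weight=tagwise_weight)
    elif np.isscalar(dispersion):
        phi = pd.Series(float(dispersion), index=cm.counts.index)
    else:
        phi = pd.Series(dispersion).reindex(cm.counts.index)

    eq, _ = _equalized_counts(cm)
    sum_pos = eq[pos_cols].sum(axis=1).round().astype(np.int64)
    sum_neg = eq[neg_cols].sum(axis=1).round().astype(np.int64)

    pvals = pd.Series(np.nan, index=cm.counts.index)
    for design_id in cm.counts.index[recovered]:
        pvals[design_id] = nb_exact_test(
            sum_pos[design_id],
            sum_neg[design_id],
            len(pos_cols),
            len(neg_cols),
            float(phi[design_id]),
        )

    fdr = pd.Series(np.nan, index=cm.counts.index)
    rec_idx = cm.counts.index[recovered]
    if len(rec_idx):
        fdr[rec_idx] = multipletests(pvals[rec_idx].to_numpy(), method="fdr_bh")[1]

    category = pd.Series("neutral", index=cm.counts.index)
    category[~recovered] = "not_recovered"
    sig = recovered & (fdr < fdr_threshold)
    category[sig & (logfc >= logfc_threshold)] = "enriched"
    category[sig & (logfc <= -logfc_threshold)] = "depleted"

    with np.errstate(divide="ignore"):
        rank_score = -np.log10(fdr.clip(lower=1e-300)) * logfc
    rank_score[~recovered] = np.nan

    out = pd.DataFrame(
        {
            "recovered": recovered,
            "logFC": logfc,
            "p_value": pvals,
            "fdr": fdr,
            "category": category,
            "rank_score": rank_score,
        }
    )
    out.index.name = "design_id"
    return out


def sequence_identity(a: str, b: str) -> float:
    """Ungapped positional identity: matching residues / max length."""
    if not a or not b:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / max(len(a), len(b))


def rank_and_select(
    results: pd.DataFrame,
    sequences: dict[str, str],
    n: int = 10,
    identity_threshold: float = 0.5,
) -> list[str]:
    """Top-n non-redundant enriched designs by rank_score.

    Greedy descent over enriched designs sorted by rank_score (ties broken
    by design_id); a candidate is skipped when its ungapped identity to any
    already-selected design reaches the threshold. Asking for more designs
    than exist returns all with a warning.
    """
    enriched = results[results["category"] == "enriched"]
    # stable sort: score descending, ties broken by design_id ascending
    order = enriched.sort_index().sort_values("rank_score", ascending=False, kind="stable")
    selected: list[str] = []
    for design_id in order.index:
        if len(selected) >= n:
            break
        seq = sequences.get(design_id)
        if seq is None:
            raise KeyError(f"no sequence for enriched design {design_id}")
        if any(
            sequence_identity(seq, sequences[prev]) >= identity_threshold
            for prev in selected
        ):
            continue
        selected.append(design_id)
    if len(enriched) < n:
        warnings.warn(f"requested {n} designs but only {len(enriched)} enriched")
    return selected


def summarize_by_team(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    logfc_threshold: float = LOGFC_THRESHOLD,
) -> pd.DataFrame:
    """Per-team recovery and hit-rate summary.

    Columns: n, pct_detected (100 when metadata has no 'detected' column),
    pct_recovered, pct_enriched, pct_depleted, pct_changed (|logFC|>=1 at
    FDR<0.05 in either direction). Teams with no designs carry n=0 and NaN
    percentages.
    """
    meta = metadata.set_index("design_id") if "design_id" in metadata.columns else metadata
    cols = ["team"] + (["detected"] if "detected" in meta.columns else [])
    joined = results.join(meta[cols])
    rows = []
    for team in sorted(meta["team"].unique()):
        grp = joined[joined["team"] == team]
        n = len(grp)
        if n == 0:
            rows.append(
                {"team": team, "n": 0, "pct_detected": 0.0, "pct_recovered": 0.0,
                 "pct_enriched": 0.0, "pct_depleted": 0.0, "pct_changed": 0.0,
                 "no_designs": True}
            )
            continue
        detected = grp["detected"].mean() * 100 if "detected" in grp.columns else 100.0
        rows.append(
            {
                "team": team,
                "n": n,
                "pct_detected": detected,
                "pct_recovered": grp["recovered"].mean() * 100,
                "pct_enriched": (grp["category"] == "enriched").mean() * 100,
                "pct_depleted": (grp["category"] == "depleted").mean() * 100,
                "pct_changed": grp["category"].isin(["enriched", "depleted"]).mean() * 100,
                "no_designs": False,
            }
        )
    out = pd.DataFrame(rows).set_index("team").sort_index()
    out.attrs["hit_rate_range"] = (
        (out["pct_enriched"].min(), out["pct_enriched"].max()) if len(out) else (np.nan, np.nan)
    )
    return out
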