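"""Expression quantification and differential expression.

FPKM quantification from raw counts, the slope-change rule for picking an
expression-activity threshold, active/common/condition-specific transcript
sets, a conditional exact test for two-condition differential expression at
the cut-offs used for drought-responsive lncRNA calling (raw p < 0.001 and
|log2FC| > 2), cross-genotype common-transcript detection, and assembly
characterization statistics (N50, GC, length summaries).

The exact test conditions on the per-transcript total count: with
dispersion 0 the conditional law of the control-condition sum is binomial
with success probability equal to the control share of the library sizes;
with dispersion d > 0 the conditional probabilities are negative-binomial
products evaluated by direct summation. Dispersion is an explicit
parameter (default 0.1): with one pooled library per condition it is not
identifiable from data, so it is stated rather than estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import classify as _cls

DEFAULT_ALPHA = 0.001
DEFAULT_LFC_MIN = 2.0
DEFAULT_DISPERSION = 0.1
DEFAULT_FPKM_GRID = np.round(np.arange(0.1, 2.01, 0.1), 10)


@dataclass
class ExpressionMatrix:
    """Raw counts with transcript lengths and sample condition labels."""

    counts: pd.DataFrame  # transcripts x samples, non-negative ints
    lengths: pd.Series  # nt per transcript
    conditions: dict[str, str]  # sample -> {control, drought}
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.lengths.reindex(self.counts.index) < 1).any():
            raise ValueError("transcript lengths must be >= 1")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def compute_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """FPKM[i,s] = counts[i,s] * 1e9 / (length[i] * library_size[s])."""
    lib = matrix.library_sizes[matrix.counts.columns]
    if (lib <= 0).any():
        raise ValueError("zero library size")
    lengths = matrix.lengths.reindex(matrix.counts.index).to_numpy(dtype=float)
    return matrix.counts * 1e9 / (lengths[:, None] * lib.to_numpy()[None, :])


def condition_fpkm(matrix: ExpressionMatrix, fpkm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean FPKM per condition (columns: control, drought)."""
    if fpkm is None:
        fpkm = compute_fpkm(matrix)
    out = {}
    for cond in ("control", "drought"):
        cols = matrix.samples_of(cond)
        if cols:
            out[cond] = fpkm[cols].mean(axis=1)
    return pd.DataFrame(out)


def select_fpkm_threshold(
    cond_fpkm: pd.DataFrame, grid: np.ndarray = DEFAULT_FPKM_GRID
) -> float:
    """Pick the activity threshold where the failing-fraction curve bends.

    For each grid point t, compute the percentage of transcripts whose FPKM
    is below t in every condition; the threshold is the interior grid point
    maximizing the discrete second difference of that curve (ties toward
    the smaller threshold). A flat/linear curve falls back to 0.5.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("grid needs at least 3 points")
    vals = cond_fpkm.to_numpy()
    failing = np.array([(vals < t).all(axis=1).mean() * 100.0 for t in grid])
    d2 = failing[2:] - 2 * failing[1:-1] + failing[:-2]
    d2 = np.round(d2, 9)  # so exact ties break toward the smaller threshold
    if d2.max() - d2.min() < 1e-9:
        return 0.5
    return float(grid[1:-1][int(np.argmax(d2))])


def active_sets(
    matrix: ExpressionMatrix, threshold: float, fpkm: pd.DataFrame | None = None
) -> dict[str, object]:
    """Actively-expressed transcripts per sample plus the condition partition.

    A transcript is active in a sample iff its FPKM >= threshold; at the
    condition level, active means mean FPKM over the condition's replicates
    >= threshold. The partition classes are common / control_only /
    drought_only / absent.
    """
    if fpkm is None:
        fpkm = compute_fpkm(matrix)
    per_sample = {s: set(fpkm.index[fpkm[s] >= threshold]) for s in fpkm.columns}
    cond = condition_fpkm(matrix, fpkm)
    in_c = cond.get("control", pd.Series(0.0, index=fpkm.index)) >= threshold
    in_d = cond.get("drought", pd.Series(0.0, index=fpkm.index)) >= threshold
    spec = pd.Series("absent", index=fpkm.index, dtype=object)
    spec[in_c & in_d] = "common"
    spec[in_c & ~in_d] = "control_only"
    spec[~in_c & in_d] = "drought_only"
    return {"per_sample": per_sample, "specificity": spec}


# ---------------------------------------------------------------------------
# Exact differential-expression test
# ---------------------------------------------------------------------------

def _exact_p_binomial(ya: int, n: int, p_control: float) -> float:
    """Two-sided conditional p: total probability of outcomes no more
    likely than the observed one."""
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p_control)
    return float(pmf[pmf <= pmf[ya] * (1 + 1e-9)].sum())


def _exact_p_nb(ya: int, n: int, frac_control: float,
                r_control: float, r_drought: float) -> float:
    """Conditional NB p-value by direct summation over the split of n."""
    k = np.arange(n + 1)
    mu_a = max(n * frac_control, 1e-12)
    mu_b = max(n * (1 - frac_control), 1e-12)
    pa = r_control / (r_control + mu_a)
    pb = r_drought / (r_drought + mu_b)
    logp = (stats.nbinom.logpmf(k, r_control, pa)
            + stats.nbinom.logpmf(n - k, r_drought, pb))
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    return float(w[w <= w[ya] * (1 + 1e-9)].sum())


def exact_de_test(
    matrix: ExpressionMatrix,
    dispersion: float = DEFAULT_DISPERSION,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-transcript conditional exact test, drought vs control.

    Condition counts are summed over replicates; the test conditions on the
    per-transcript total. log2FC uses library-size-normalized condition
    sums with a 0.5 pseudocount. Status is up/down when raw p < alpha and
    |log2FC| > lfc_min (``adjust=True`` thresholds the BH q-value instead).
    """
    conds = {matrix.conditions[s] for s in matrix.counts.columns}
    if conds - {"control", "drought"}:
        raise ValueError(f"unsupported conditions: {sorted(conds)}")
    if len(conds) != 2:
        raise ValueError("both a control and a drought condition are required")
    ctrl, drt = matrix.samples_of("control"), matrix.samples_of("drought")
    ya = matrix.counts[ctrl].sum(axis=1).to_numpy()
    yb = matrix.counts[drt].sum(axis=1).to_numpy()
    La = float(matrix.library_sizes[ctrl].sum())
    Lb = float(matrix.library_sizes[drt].sum())
    frac = La / (La + Lb)
    r_ctrl = len(ctrl) / dispersion if dispersion > 0 else np.inf
    r_drt = len(drt) / dispersion if dispersion > 0 else np.inf

    n_tot = ya + yb
    pvals = np.ones(len(n_tot))
    for i, (a, n) in enumerate(zip(ya, n_tot)):
        if n == 0:
            continue
        if dispersion <= 0:
            pvals[i] = _exact_p_binomial(int(a), int(n), frac)
        else:
            pvals[i] = _exact_p_nb(int(a), int(n), frac, r_ctrl, r_drt)
    pvals = np.clip(pvals, 0.0, 1.0)
    log2fc = np.log2(((yb + 0.5) / Lb) / ((ya + 0.5) / La))
    qvals = bh_adjust(pvals)
    crit = qvals if adjust else pvals
    status = np.where(
        (crit < alpha) & (log2fc > lfc_min), "up",
        np.where((crit < alpha) & (log2fc < -lfc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "q_value": qvals, "status": status},
        index=matrix.counts.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def attach_specificity(de: pd.DataFrame, specificity: pd.Series) -> pd.DataFrame:
    out = de.copy()
    out["sample_specificity"] = specificity.reindex(de.index).fillna("absent")
    return out


# ---------------------------------------------------------------------------
# Cross-genotype comparison
# ---------------------------------------------------------------------------

def common_across_genotypes(
    set_a: dict[str, str],
    set_b: dict[str, str],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    prefilter_k: int | None = None,
) -> pd.Series:
    """Label each transcript of set_a 'common' or 'specific' against set_b.

    Common means some local alignment to a set_b transcript reaches both
    the identity threshold and coverage (alignment columns / query length)
    of at least ``min_coverage`` percent.
    """
    labels = pd.Series("specific", index=list(set_a), dtype=object)
    if not set_b:
        return labels
    hits = _cls.homology_search(
        set_a, set_b, mode="nucl", min_identity=min_identity,
        min_length=1, max_evalue=np.inf, database="genotype",
        prefilter_k=prefilter_k,
    )
    for qid, hit in hits.items():
        if 100.0 * hit.alignment_length / len(set_a[qid]) >= min_coverage:
            labels[qid] = "common"
    return labels


# ---------------------------------------------------------------------------
# Assembly characterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    median_len: float
    mean_len: float
    total_len_mb: float
    gc_percent: float
    n50: int


def assembly_stats(sequences: dict[str, str]) -> AssemblyStats:
    """Contig-style summary: N50 is the largest L such that contigs of
    length >= L hold at least half the total assembled length."""
    if not sequences:
        raise ValueError("empty transcript set")
    lengths = np.sort(np.array([len(s) for s in sequences.values()]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2)])
    gc = sum(s.count("G") + s.count("C") for s in sequences.values())
    return AssemblyStats(
        n_transcripts=len(lengths),
        median_len=float(np.median(lengths)),
        mean_len=float(lengths.mean()),
        total_len_mb=total / 1e6,
        gc_percent=100.0 * gc / total,
        n50=n50,
    )


def characterize(
    sequences: dict[str, str], classes: pd.Series, length_bins: int = 20
) -> pd.DataFrame:
    """Per-class length/GC summary (mean/min/max length, mean/range GC)."""
    rows = []
    for cls in sorted(classes.dropna().unique()):
        ids = [i for i in classes.index[classes == cls] if i in sequences]
        if not ids:
            continue
        lens = np.array([len(sequences[i]) for i in ids])
        gcs = np.array([
            100.0 * (sequences[i].count("G") + sequences[i].count("C")) / len(sequences[i])
            for i in ids
        ])
        rows.append({
            "class": cls, "n": len(ids),
            "mean_len": lens.mean(), "min_len": int(lens.min()), "max_len": int(lens.max()),
            "mean_gc": gcs.mean(), "min_gc": gcs.min(), "max_gc": gcs.max(),
        })
    return pd.DataFrame(rows).set_index("class")


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative qRT-PCR expression by the 2^-dCt rule."""
    return float(2.0 ** -(ct_target - ct_reference))
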