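"""Experiment orchestration: variant x frequency sweeps and statistics.

Runs the recognition model over a synthetic corpus for every requested
variant and precision-modulation frequency, collects per-sentence metrics
into a long-format table, and provides the statistical summaries used for
model comparison: percentile-bootstrap confidence intervals of the mean,
paired Wilcoxon signed-rank tests with Bonferroni correction, Friedman
tests across frequencies with corrected post-hoc pairwise comparisons, and
a two-factor ANOVA (variant as a discrete factor, frequency continuous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import SyllableInventory, make_corpus, make_inventory
from .generative import VARIANT_NAMES, variant_config
from .inference import InferenceOptions, invert
from .metrics import bic, evaluate

DEFAULT_PSIS = (2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

# canonical study conditions for the default synthetic corpus
DEFAULT_CORPUS = dict(
    n_sentences=30,
    inventory_size=10,
    n_syl=8,
    mean_dur_ms=200.0,
    cv=0.3,
    noise_sd=0.05,
)
DEFAULT_INVENTORY_SEED = 1
DEFAULT_CORPUS_SEED = 0

METRIC_COLUMNS = ("overlap", "ent_overlap", "lcs_ratio", "integration", "loglik")


@dataclass(frozen=True)
class SweepSpec:
    """Which variants and modulation frequencies to sweep."""

    variants: tuple[str, ...] = VARIANT_NAMES
    psis: tuple[float, ...] = DEFAULT_PSIS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants or not self.psis:
            raise ValueError("variants and psis must be non-empty")
        for v in self.variants:
            if v not in VARIANT_NAMES:
                raise ValueError(f"unknown variant {v!r}")


def default_corpus(
    inventory_seed: int = DEFAULT_INVENTORY_SEED,
    corpus_seed: int = DEFAULT_CORPUS_SEED,
    n_sentences: int | None = None,
):
    """The canonical study corpus: (inventory, [(sentence, arrays), ...])."""
    params = dict(DEFAULT_CORPUS)
    if n_sentences is not None:
        params["n_sentences"] = n_sentences
    inv = make_inventory(params.pop("inventory_size"), seed=inventory_seed)
    corpus = make_corpus(params.pop("n_sentences"), inv, seed=corpus_seed, **params)
    return inv, corpus


def frequency_sweep(
    spec: SweepSpec,
    corpus,
    inventory: SyllableInventory,
    opts: InferenceOptions | None = None,
) -> pd.DataFrame:
    """Run every sentence under every (variant, psi) condition.

    The stationary baseline is computed once and broadcast to every
    requested psi (its dynamics do not depend on the modulation frequency).
    Per-sentence failures are recorded with their status and the run
    continues. Fully reproducible from the corpus and the options' seed.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if opts is None:
        opts = InferenceOptions(seed=spec.master_seed)
    rows = []

    def run_condition(variant: str, psi: float):
        cfg = variant_config(variant)
        out = []
        for sid, (sent, stim) in enumerate(corpus):
            trace = invert(stim, inventory, cfg, psi=psi, opts=opts)
            rep = evaluate(trace, sent)
            out.append((sid, rep))
        return out

    for variant in spec.variants:
        if variant == "stationary":
            baseline = run_condition("stationary", spec.psis[0])
            for psi in spec.psis:
                for sid, rep in baseline:
                    rows.extend(_metric_rows(sid, variant, psi, rep))
        else:
            for psi in spec.psis:
                for sid, rep in run_condition(variant, psi):
                    rows.extend(_metric_rows(sid, variant, psi, rep))
    return pd.DataFrame(
        rows, columns=["sentence_id", "variant", "psi", "metric", "value", "status"]
    )


def _metric_rows(sid, variant, psi, rep):
    for m in METRIC_COLUMNS:
        yield (sid, variant, float(psi), m, getattr(rep, m), rep.status)


def bootstrap_summary(
    values, reps: int = 10000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: (mean, ci_low, ci_high) at 95%."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(reps, len(v)))
    means = v[idx].mean(axis=1)
    return float(v.mean()), float(np.percentile(means, 2.5)), float(
        np.percentile(means, 97.5)
    )


def summarize(
    table: pd.DataFrame, metric: str = "overlap", reps: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Mean and bootstrap CI per (variant, psi) condition for one metric."""
    out = []
    sub = table[(table.metric == metric) & (table.status == "ok")]
    for (variant, psi), grp in sub.groupby(["variant", "psi"]):
        mean, lo, hi = bootstrap_summary(grp.value.to_numpy(), reps=reps, seed=seed)
        out.append((variant, psi, len(grp), mean, lo, hi))
    return pd.DataFrame(
        out, columns=["variant", "psi", "n", "mean", "ci_low", "ci_high"]
    )


def _paired_values(table, metric, cond_a, cond_b):
    """Per-sentence value pairs for two (variant, psi) conditions, using
    exactly the sentences that succeeded under both."""
    sub = table[table.metric == metric]
    a = sub[(sub.variant == cond_a[0]) & (sub.psi == cond_a[1])]
    b = sub[(sub.variant == cond_b[0]) & (sub.psi == cond_b[1])]
    merged = a.merge(b, on="sentence_id", suffixes=("_a", "_b"))
    merged = merged[(merged.status_a == "ok") & (merged.status_b == "ok")]
    if merged.empty:
        raise ValueError("no paired sentences for the requested conditions")
    return merged.value_a.to_numpy(), merged.value_b.to_numpy()


def paired_tests(
    table: pd.DataFrame,
    baseline: tuple[str, float],
    contrasts: list[tuple[str, float]],
    metric: str = "overlap",
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test of each contrast against the baseline.

    Sentences are paired by id; any sentence that failed in either member
    of a pair is dropped from that pair. Significance uses the Bonferroni
    threshold alpha/m (m defaults to the number of contrasts; the reference
    sweep uses m = 8, one per tested frequency).
    """
    if m is None:
        m = len(contrasts)
    rows = []
    for cond in contrasts:
        va, vb = _paired_values(table, metric, cond, baseline)
        diffs = va - vb
        if np.allclose(diffs, 0):
            stat_val, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(va, vb)
            stat_val, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variant": cond[0],
                "psi": cond[1],
                "n_pairs": len(va),
                "statistic": stat_val,
                "p": p,
                "significant": p < alpha / m,
                "threshold": alpha / m,
            }
        )
    return pd.DataFrame(rows)


def friedman_by_frequency(
    table: pd.DataFrame, variant: str, metric: str = "overlap", alpha: float = 0.05
) -> dict:
    """Friedman test across psis for one variant, plus Bonferroni-corrected
    post-hoc pairwise signed-rank comparisons."""
    sub = table[
        (table.metric == metric) & (table.variant == variant) & (table.status == "ok")
    ]
    wide = sub.pivot_table(index="sentence_id", columns="psi", values="value")
    wide = wide.dropna()
    psis = list(wide.columns)
    if len(psis) < 3:
        raise ValueError("Friedman test needs at least 3 frequencies")
    chi2, p = stats.friedmanchisquare(*[wide[c].to_numpy() for c in psis])
    pairs = []
    n_pairs = len(psis) * (len(psis) - 1) // 2
    for i in range(len(psis)):
        for j in range(i + 1, len(psis)):
            a, b = wide[psis[i]].to_numpy(), wide[psis[j]].to_numpy()
            if np.allclose(a - b, 0):
                pp = 1.0
            else:
                pp = float(stats.wilcoxon(a, b).pvalue)
            pairs.append(
                {
                    "psi_a": psis[i],
                    "psi_b": psis[j],
                    "p_corrected": min(pp * n_pairs, 1.0),
                    "significant": pp * n_pairs < alpha,
                }
            )
    return {"chi2": float(chi2), "p": float(p), "posthoc": pd.DataFrame(pairs)}


def variant_anova(table: pd.DataFrame, metric: str = "overlap") -> pd.DataFrame:
    """Two-factor ANOVA: variant (discrete) x psi (continuous), with
    interaction, on the per-sentence metric values."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    sub = table[
        (table.metric == metric)
        & (table.status == "ok")
        & (table.variant != "stationary")
    ].copy()
    model = smf.ols("value ~ C(variant) * psi", data=sub).fit()
    return anova_lm(model, typ=2)


def bic_by_condition(table: pd.DataFrame) -> pd.DataFrame:
    """BIC per (variant, psi) from the per-sentence log-likelihoods."""
    rows = []
    sub = table[(table.metric == "loglik") & (table.status == "ok")]
    for (variant, psi), grp in sub.groupby(["variant", "psi"]):
        n_params = variant_config(variant).n_state_variables
        rows.append(
            (variant, psi, len(grp), bic(grp.value.to_numpy(), len(grp), n_params))
        )
    return pd.DataFrame(rows, columns=["variant", "psi", "n_sentences", "bic"])
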