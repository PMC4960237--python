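"""Independent oracles the test suite checks the implementation against.

Everything here is deliberately written from first principles — pure
Python loops and closed-form probability — and must stay independent of
the code paths under test.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import norm

from omproteome.types import Compartment, Fraction

# ---------------------------------------------------------------------------
# brute-force recomputation of LFQ / fold-change quantities on tiny tables
# ---------------------------------------------------------------------------


def brute_shares(log10_values: dict, detected: dict, detected_only=True) -> dict:
    """Per-protein linear-scale shares for one sample.

    ``log10_values``/``detected`` map protein id -> value/flag.
    """
    linear = {}
    for pid, v in log10_values.items():
        if detected_only and not detected[pid]:
            linear[pid] = 0.0
        else:
            linear[pid] = 10.0 ** v
    total = sum(linear.values())
    return {pid: x / total for pid, x in linear.items()}


def brute_compartment_shares(shares: dict, labels: dict) -> dict:
    out: dict = {}
    for pid, s in shares.items():
        comp = labels.get(pid, Compartment.UNKNOWN)
        out[comp] = out.get(comp, 0.0) + s
    return out


def brute_enrichment(shares_t: dict, shares_r: dict, comp) -> float:
    return shares_t[comp] / shares_r[comp]


def brute_impute(log10_values: dict, detected: dict, offset, floor) -> dict:
    detected_vals = [v for pid, v in log10_values.items() if detected[pid]]
    sub = max(min(detected_vals) - offset, floor)
    return {
        pid: (v if detected[pid] else sub) for pid, v in log10_values.items()
    }


def brute_fold_change(a: float, b: float) -> float:
    return 10.0 ** (a - b)


# ---------------------------------------------------------------------------
# closed-form log-normal mixture expectations for enrichment
# ---------------------------------------------------------------------------

LN10 = math.log(10.0)


def _censored_moment(mu, sigma, limit, order=1):
    """E[10^(order*X) * 1{X >= limit}] for X ~ N(mu, sigma^2)."""
    b = order * LN10
    # E[e^{bX} 1{X>=L}] = e^{b mu + b^2 s^2 / 2} * Phi((mu + b s^2 - L)/s)
    e = math.exp(b * mu + 0.5 * b * b * sigma * sigma)
    tail = norm.cdf((mu + b * sigma * sigma - limit) / sigma)
    return e * tail


def _detect_prob(mu, sigma, limit):
    return float(norm.sf((limit - mu) / sigma))


def expected_enrichment(cfg, fraction_target=Fraction.OM_SARKOSYL,
                        fraction_reference=Fraction.WHOLE_PROTEOME):
    """Closed-form expectation and delta-method SD of the OM enrichment factor.

    Assumes detected-only shares with ground-truth compartment labels,
    evaluated on glucose-condition samples (no condition effects), with
    the mucin-exclusive OM proteins removed (forced undetected under
    glucose).  Derived from the generator's log-normal mixture: for each
    compartment c with expected count n_c and mean mu_cf, the detected
    intensity sum has per-term moments
    E[t] = e^{b mu + b^2 s^2/2} Phi((mu + b s^2 - L)/s), b = ln 10.
    """
    sigma = cfg.lfq_sd
    limit = cfg.detection_limit
    comps = list(cfg.compartment_proportions)

    def stratum_counts():
        counts = {}
        for c in comps:
            counts[c] = cfg.n_proteins * cfg.compartment_proportions[c]
        # mucin-exclusive OM proteins are censored under glucose
        counts[Compartment.OUTER_MEMBRANE] -= cfg.n_exclusive_per_condition
        return counts

    counts = stratum_counts()

    def share_stats(fraction):
        m1 = {}
        var = {}
        for c in comps:
            mu = cfg.lfq_means[(c, fraction)]
            et = _censored_moment(mu, sigma, limit, order=1)
            et2 = _censored_moment(mu, sigma, limit, order=2)
            n_c = counts[c]
            m1[c] = n_c * et
            var[c] = n_c * max(et2 - et * et, 0.0)
        total = sum(m1.values())
        om = Compartment.OUTER_MEMBRANE
        share = m1[om] / total
        # delta method on log(share) = log S_om - log S_total
        v = (1.0 / m1[om] - 1.0 / total) ** 2 * var[om]
        for c in comps:
            if c is not om:
                v += (1.0 / total) ** 2 * var[c]
        return share, v

    share_t, vlog_t = share_stats(fraction_target)
    share_r, vlog_r = share_stats(fraction_reference)
    factor = share_t / share_r
    sd = factor * math.sqrt(vlog_t + vlog_r)
    return factor, sd


# ---------------------------------------------------------------------------
# closed-form classifier recovery under per-field predictor corruption
# ---------------------------------------------------------------------------


def expected_om_recovery(eps, p_lipo, p_barrel, p_signal, cutoff=0.5):
    """P(>=1 OM criterion fires | true OM protein).

    Enumerates the Bernoulli ground-truth attributes (lipoprotein,
    barrel, signal) and applies the corruption model: with probability
    eps a field is replaced by a uniform draw over the other admissible
    values (booleans flip; the secretion score resamples Uniform(0,1)).
    """
    total = 0.0
    for lipo, barrel, signal in itertools.product([0, 1], repeat=3):
        w = (
            (p_lipo if lipo else 1 - p_lipo)
            * (p_barrel if barrel else 1 - p_barrel)
            * (p_signal if signal else 1 - p_signal)
        )
        # C1: both labels stay OM (corruption always leaves OM)
        p_c1 = (1 - eps) ** 2
        # C2: observed class == lipoprotein
        if lipo:
            p_c2 = 1 - eps
        else:
            p_c2 = eps / 2  # corrupted uniform over the other two classes
        # C3: observed category >= 1 (true category is 1 or 0)
        if barrel:
            p_c3 = (1 - eps) + eps * (4.0 / 5.0)
        else:
            p_c3 = eps  # corrupted uniform over {1..5}, all >= 1
        # C4: observed signal False AND observed score > cutoff
        p_nosig = eps if signal else (1 - eps)
        true_score = 0.2 if signal else 0.8
        p_score = (1 - eps) * (1.0 if true_score > cutoff else 0.0) + eps * (
            1 - cutoff
        )
        p_c4 = p_nosig * p_score
        p_none = (1 - p_c1) * (1 - p_c2) * (1 - p_c3) * (1 - p_c4)
        total += w * (1 - p_none)
    return total


# ---------------------------------------------------------------------------
# closed-form power of the >threshold-fold rule
# ---------------------------------------------------------------------------


def fold_rule_power(effect, sigma, threshold=10.0):
    """P(|log10 ratio| > log10(threshold)) for a true log10 effect.

    The observed log10 difference between two single samples is
    N(effect, 2 sigma^2).
    """
    s = sigma * math.sqrt(2.0)
    t = math.log10(threshold)
    return float(norm.sf((t - effect) / s) + norm.cdf((-t - effect) / s))
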