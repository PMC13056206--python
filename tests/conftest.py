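import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def literal_gn(e, k):
    """Independent literal transcription of the self-normalized statistic
    for a single candidate k, using nothing but plain loops; the oracle the
    optimized profile computation is checked against."""
    e = np.asarray(e, dtype=float)
    n = len(e)
    mean1 = sum(e[:k]) / k
    mean2 = sum(e[k:]) / (n - k)
    num = n * abs(mean1 - mean2)
    ssq = 0.0
    acc = 0.0
    for t in range(k):
        acc += e[t] - mean1
        ssq += acc * acc
    acc = 0.0
    for t in range(k, n):
        acc += e[t] - mean2
        ssq += acc * acc
    den = (ssq / n) ** 0.5
    if den == 0.0:
        return float("inf") if num > 0 else 0.0
    return num / den


def literal_competitors(y, e):
    """Term-by-term transcription of the likelihood-score and maximum-type
    statistics (untrimmed max over k = 1..n)."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    n = len(y)
    tau1_sq = sum((y[t] - e[t]) ** 2 * e[t] ** 2 for t in range(n)) / n
    tau2_sq = sum(e[t] ** 4 for t in range(n)) / n - (
        sum(e[t] ** 2 for t in range(n)) / n
    ) ** 2
    total_a = sum((y[t] - e[t]) * e[t] for t in range(n))
    total_b = sum(e[t] ** 2 for t in range(n))
    t_ls = -np.inf
    t_max = -np.inf
    for k in range(1, n + 1):
        a = sum((y[t] - e[t]) * e[t] for t in range(k)) - k / n * total_a
        b = sum(e[t] ** 2 for t in range(k)) - k / n * total_b
        t_ls = max(t_ls, abs(a) ** 2 / (n * tau1_sq) + abs(b) ** 2 / (n * tau2_sq))
        t_max = max(
            t_max,
            max(abs(a) / (n**0.5 * tau1_sq**0.5), abs(b) / (n**0.5 * tau2_sq**0.5)),
        )
    return t_ls, t_max
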