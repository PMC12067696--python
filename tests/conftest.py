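import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_de_pair():
    """Two tiny DE tables sharing a 4-gene universe with known signs."""
    s1 = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C", "D"],
            "log2fc": [1.0, -1.0, 2.0, -0.5],
            "pvalue": [0.01, 0.02, 0.03, 0.04],
            "fdr": [0.04, 0.04, 0.04, 0.04],
        }
    )
    s2 = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C", "D"],
            "log2fc": [0.5, -2.0, -1.0, 0.25],
            "pvalue": [0.01, 0.02, 0.03, 0.04],
            "fdr": [0.04, 0.04, 0.04, 0.04],
        }
    )
    return s1, s2


@pytest.fixture
def ranked_five():
    """The 5-gene ranked list used in the worked running-sum examples."""
    return pd.DataFrame(
        {"gene_id": ["a", "b", "c", "d", "e"], "stat": [5.0, 4.0, 3.0, 2.0, 1.0]}
    )


def brute_force_running_sum(stats, hit_mask, weight_exponent=1.0):
    """Independent O(N) oracle for the weighted KS enrichment score.

    Walks the ranked list once, accumulating |stat|^w / sum_hits at hits
    and -1/(N - n_hits) at misses; returns (es, peak_index, running).
    """
    n = len(stats)
    k = int(np.sum(hit_mask))
    denom = float(np.sum(np.abs(np.asarray(stats)[hit_mask]) ** weight_exponent))
    running = []
    total = 0.0
    for i in range(n):
        if hit_mask[i]:
            total += (
                (abs(stats[i]) ** weight_exponent) / denom if denom > 0 else 1.0 / k
            )
        else:
            total -= 1.0 / (n - k)
        running.append(total)
    running = np.array(running)
    best, peak = 0.0, 0
    for i, v in enumerate(running):
        if abs(v) > abs(best):
            best, peak = v, i
    return best, peak, running
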