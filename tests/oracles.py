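"""Independent oracle implementations shared by test modules."""
from scipy import stats


def oracle_grubbs(values, alpha=0.05):
    """Iterative two-sided Grubbs built directly from the t-distribution
    critical-value formula G_crit = ((n-1)/sqrt(n)) sqrt(t^2/(n-2+t^2)),
    t the upper alpha/(2n) quantile with n-2 df; pure-Python, independent
    of the package implementation."""
    x = list(map(float, values))
    idx = list(range(len(x)))
    removed = []
    while len(x) >= 3:
        n = len(x)
        mean = sum(x) / n
        s = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
        if s == 0:
            break
        devs = [abs(v - mean) for v in x]
        i = devs.index(max(devs))
        G = devs[i] / s
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = ((n - 1) / n ** 0.5) * (t * t / (n - 2 + t * t)) ** 0.5
        if G > crit:
            removed.append(idx.pop(i))
            x.pop(i)
        else:
            break
    return removed
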