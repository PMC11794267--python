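"""Independent naive-loop oracle implementations of the feature catalog.

Deliberately written with plain Python loops and direct DFTs (no shared code
with the package) so they can certify the vectorized implementations.
"""

import math


def _mean(x):
    return sum(x) / len(x)


def _central_moment(x, k):
    m = _mean(x)
    return sum((v - m) ** k for v in x) / len(x)


def _quantile(x, q):
    """Linear-interpolation quantile (the numpy default convention)."""
    s = sorted(x)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_periodogram(x, fs):
    """One-sided density periodogram with the mean removed, via direct DFT."""
    N = len(x)
    m = _mean(x)
    xd = [v - m for v in x]
    M = N // 2 + 1
    freqs, power = [], []
    for k in range(M):
        re = sum(xd[n] * math.cos(2 * math.pi * k * n / N) for n in range(N))
        im = -sum(xd[n] * math.sin(2 * math.pi * k * n / N) for n in range(N))
        p = (re * re + im * im) / (fs * N)
        if 0 < k < N / 2:
            p *= 2.0
        freqs.append(k * fs / N)
        power.append(p)
    return freqs, power


def _band(x, fs):
    freqs, power = naive_periodogram(x, fs)
    pairs = [(f, p) for f, p in zip(freqs, power) if 20.0 <= f <= 500.0]
    return [f for f, _ in pairs], [p for _, p in pairs]


def naive_apen(x, m, r):
    N = len(x)
    if N <= m + 1:
        return 0.0

    def phi(mm):
        tpl = [x[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for a in tpl:
            cnt = 0
            for b in tpl:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    cnt += 1
            total += math.log(cnt / len(tpl))
        return total / len(tpl)

    return phi(m) - phi(m + 1)


def naive_feature(name, x, fs, eps_zc=0.0, eps_ssc=0.0, theta_frac=0.1,
                  v_order=3, apen_m=2, apen_r_frac=0.2, card_tau=0.01,
                  fr_split=250.0, log_eps=1e-12):
    x = [float(v) for v in x]
    N = len(x)
    mean = _mean(x)
    sd = math.sqrt(_central_moment(x, 2))
    d = [x[i + 1] - x[i] for i in range(N - 1)]
    var_s = sum((v - mean) ** 2 for v in x) / (N - 1)
    std_s = math.sqrt(var_s)
    damv = sum(abs(v) for v in d) / (N - 1)
    cv = std_s / max(abs(mean), log_eps)

    if name in ("IEMG", "IAV"):
        return sum(abs(v) for v in x)
    if name == "MAV":
        return sum(abs(v) for v in x) / N
    if name == "RMS":
        return math.sqrt(sum(v * v for v in x) / N)
    if name == "VAR":
        return var_s
    if name == "STD":
        return std_s
    if name == "WL":
        return sum(abs(v) for v in d)
    if name == "ZC":
        return sum(1 for i in range(N - 1)
                   if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps_zc)
    if name == "SSC":
        return sum(1 for i in range(1, N - 1)
                   if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > eps_ssc)
    if name == "MAD":
        return sum(abs(v - mean) for v in x) / N
    if name == "SSI":
        return sum(v * v for v in x)
    if name == "AE":
        return sum(v * v for v in x) / N
    if name == "SKEW":
        return _central_moment(x, 3) / max(_central_moment(x, 2), log_eps) ** 1.5
    if name == "KURT":
        return _central_moment(x, 4) / max(_central_moment(x, 2), log_eps) ** 2 - 3.0
    if name == "MMAV1":
        tot = 0.0
        for i in range(1, N + 1):
            w = 1.0 if 0.25 * N <= i <= 0.75 * N else 0.5
            tot += w * abs(x[i - 1])
        return tot / N
    if name == "MMAV2":
        tot = 0.0
        for i in range(1, N + 1):
            if i < 0.25 * N:
                w = 4.0 * i / N
            elif i > 0.75 * N:
                w = 4.0 * (N - i) / N
            else:
                w = 1.0
            tot += w * abs(x[i - 1])
        return tot / N
    if name == "TM3":
        return abs(sum(v ** 3 for v in x) / N)
    if name == "TM4":
        return sum(v ** 4 for v in x) / N
    if name == "TM5":
        return abs(sum(v ** 5 for v in x) / N)
    if name == "VO":
        return (sum(abs(v) ** v_order for v in x) / N) ** (1.0 / v_order)
    if name == "LD":
        return math.exp(sum(math.log(abs(v) + log_eps) for v in x) / N)
    if name in ("DAMV", "AAC"):
        return damv
    if name == "DASDV":
        return math.sqrt(sum(v * v for v in d) / (N - 1))
    if name == "MFL":
        return math.log10(max(math.sqrt(sum(v * v for v in d)), log_eps))
    if name == "LDAMV":
        return math.log(max(damv, log_eps))
    if name == "LCOV":
        return math.log(max(cv, log_eps))
    if name == "WAMP":
        theta = theta_frac * sd
        return sum(1 for v in d if abs(v) > theta)
    if name == "CV":
        return cv
    if name == "HMOB":
        var_x = _central_moment(x, 2)
        if var_x <= log_eps:
            return 0.0
        md = _mean(d)
        var_d = sum((v - md) ** 2 for v in d) / len(d)
        return math.sqrt(var_d / var_x)
    if name == "ASS":
        return abs(sum(math.sqrt(abs(v)) for v in x))
    if name == "APEN":
        if sd == 0:
            return 0.0
        return naive_apen(x, apen_m, apen_r_frac * sd)
    if name == "CARD":
        tau = card_tau * sd
        if tau <= 0:
            return 1.0
        return float(len({round(v / tau) for v in x}))
    if name == "IQR":
        return _quantile(x, 0.75) - _quantile(x, 0.25)
    if name == "ME":
        return max(v * v for v in x)
    if name in ("PF", "MP", "MNF", "FR", "TP", "MMF"):
        f, p = _band(x, fs)
        if name == "PF":
            best = max(range(len(p)), key=lambda i: p[i])
            return f[best]
        if name == "MP":
            return sum(p) / len(p)
        if name == "MNF":
            return sum(fi * pi for fi, pi in zip(f, p)) / max(sum(p), log_eps)
        if name == "FR":
            low = sum(pi for fi, pi in zip(f, p) if fi <= fr_split)
            high = sum(pi for fi, pi in zip(f, p) if fi > fr_split)
            return low / max(high, log_eps)
        if name == "TP":
            return sum(p)
        if name == "MMF":
            a = [math.sqrt(pi) for pi in p]
            return sum(fi * ai for fi, ai in zip(f, a)) / max(sum(a), log_eps)
    raise KeyError(name)


def naive_anova_F(groups):
    """Sum-of-squares one-way ANOVA F, df_between, df_within."""
    allv = [v for g in groups for v in g]
    grand = _mean(allv)
    ssb = sum(len(g) * (_mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - _mean(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def naive_window_count(T, W, overlap):
    """Enumerate valid window start positions by brute force."""
    step = round(W * (1.0 - overlap))
    count = 0
    s = 0
    while s + W <= T:
        count += 1
        s += step
    return count
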