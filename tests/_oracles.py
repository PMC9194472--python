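"""Independent brute-force oracles for descriptor and metric checks.

Everything here is written as naive loops over positions, pairs and
occurrences — deliberately sharing no code path with the package — so
the tests compare two independent routes to the same numbers.
"""

import math

from glutarkit.encoders import CTD_ATTRIBUTES, PAAC_SCALES
from glutarkit.peptide_io import ALPHABET


def strip_x(seq):
    return "".join(c for c in seq if c != "X")


def aac_oracle(seq):
    s = strip_x(seq)
    out = []
    for a in ALPHABET:
        n = 0
        for c in s:
            if c == a:
                n += 1
        out.append(n / len(s))
    return out


def eaac_oracle(seq, window=5):
    out = []
    for start in range(len(seq) - window + 1):
        win = strip_x(seq[start:start + window])
        for a in ALPHABET:
            n = sum(1 for c in win if c == a)
            out.append(n / len(win) if win else 0.0)
    return out


def _groups(attr):
    return CTD_ATTRIBUTES[attr]


def ctdc_oracle(seq):
    s = strip_x(seq)
    out = []
    for attr in CTD_ATTRIBUTES:
        for grp in _groups(attr):
            n = sum(1 for c in s if c in grp)
            out.append(n / len(s))
    return out


def ctdt_oracle(seq):
    s = strip_x(seq)
    out = []
    for attr in CTD_ATTRIBUTES:
        g1, g2, g3 = _groups(attr)
        for ga, gb in ((g1, g2), (g1, g3), (g2, g3)):
            n = 0
            for i in range(len(s) - 1):
                a, b = s[i], s[i + 1]
                if (a in ga and b in gb) or (a in gb and b in ga):
                    n += 1
            out.append(n / (len(s) - 1))
    return out


def ctdd_oracle(seq):
    s = strip_x(seq)
    n = len(s)
    out = []
    for attr in CTD_ATTRIBUTES:
        for grp in _groups(attr):
            positions = [i + 1 for i, c in enumerate(s) if c in grp]
            k = len(positions)
            if k == 0:
                out.extend([0.0] * 5)
            else:
                for q in (None, 0.25, 0.50, 0.75, 1.0):
                    idx = 1 if q is None else max(1, math.ceil(q * k))
                    out.append(positions[idx - 1] / n)
    return out


def _std_scale(name):
    vals = [PAAC_SCALES[name][a] for a in ALPHABET]
    mean = sum(vals) / 20
    var = sum((v - mean) ** 2 for v in vals) / 20
    sd = math.sqrt(var)
    return {a: (PAAC_SCALES[name][a] - mean) / sd for a in ALPHABET}


def paac_oracle(seq, lam=15, weight=0.05):
    s = strip_x(seq)
    L = len(s)
    scales = [_std_scale(n) for n in ("hydrophobicity", "hydrophilicity", "sidechain_mass")]
    f = aac_oracle(s)
    taus = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            j = sum((sc[s[i + k]] - sc[s[i]]) ** 2 for sc in scales) / 3
            total += j
        taus.append(total / (L - k))
    denom = sum(f) + weight * sum(taus)
    return [v / denom for v in f] + [weight * t / denom for t in taus]


def apaac_oracle(seq, lam=15, weight=0.05):
    s = strip_x(seq)
    L = len(s)
    h1 = _std_scale("hydrophobicity")
    h2 = _std_scale("hydrophilicity")
    f = aac_oracle(s)
    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(h1[s[i]] * h1[s[i + j]] for i in range(L - j)) / (L - j))
        taus.append(sum(h2[s[i]] * h2[s[i + j]] for i in range(L - j)) / (L - j))
    denom = sum(f) + weight * sum(taus)
    return [v / denom for v in f] + [weight * t / denom for t in taus]


def auc_oracle(labels, scores):
    """All positive/negative pairs, half credit for ties."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def metrics_oracle(labels, preds):
    """Recompute the seven threshold metrics from raw vectors."""
    tp = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 1)
    tn = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 0)
    fp = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 1)
    fn = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 0)

    def div(a, b):
        return a / b if b else 0.0

    rec = div(tp, tp + fn)
    spe = div(tn, tn + fp)
    pre = div(tp, tp + fp)
    acc = div(tp + tn, tp + tn + fp + fn)
    f1 = div(2 * rec * pre, rec + pre)
    mcc = div(tp * tn - fp * fn,
              math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return dict(rec=rec, spe=spe, pre=pre, acc=acc, mcc=mcc, f1=f1)
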