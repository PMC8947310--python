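"""Independent straight-line reference implementations used as oracles.

Deliberately written with explicit Python loops and scalar math so they
share no code (and no vectorisation choices) with the package.
"""

import math


def reference_squash(vec):
    n2 = math.fsum(v * v for v in vec)
    if n2 == 0.0:
        return [0.0 for _ in vec]
    norm = math.sqrt(n2)
    scale = (n2 / (1.0 + n2)) / norm
    return [scale * v for v in vec]


def reference_routing(u_hat, iterations):
    """Dynamic routing by agreement on a nested-list u_hat[i][j][d].

    Logits start at zero; per round: couplings = per-i softmax over j,
    s_j = sum_i c_ij u_hat[j|i], v_j = squash(s_j); every round except the
    last adds the agreement u_hat . v_j to the logits.
    Returns (v, b, c) as nested lists.
    """
    n_in = len(u_hat)
    n_out = len(u_hat[0])
    d = len(u_hat[0][0])
    b = [[0.0] * n_out for _ in range(n_in)]
    v = c = None
    for r in range(iterations):
        c = []
        for i in range(n_in):
            mx = max(b[i])
            exps = [math.exp(x - mx) for x in b[i]]
            z = math.fsum(exps)
            c.append([e / z for e in exps])
        s = [[math.fsum(c[i][j] * u_hat[i][j][k] for i in range(n_in)) for k in range(d)]
             for j in range(n_out)]
        v = [reference_squash(s[j]) for j in range(n_out)]
        if r < iterations - 1:
            for i in range(n_in):
                for j in range(n_out):
                    b[i][j] += math.fsum(u_hat[i][j][k] * v[j][k] for k in range(d))
    return v, b, c


def reference_one_vs_rest(cm, c):
    """Binary collapse of a confusion matrix (rows truth, cols prediction)."""
    n = sum(sum(row) for row in cm)
    tp = cm[c][c]
    fn = sum(cm[c]) - tp
    fp = sum(row[c] for row in cm) - tp
    tn = n - tp - fn - fp
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec
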