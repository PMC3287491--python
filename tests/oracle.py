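"""Independent brute-force implementations used as test oracles.

Everything here is written as plain per-fold / per-candidate loops with its
own tiny classifiers, sharing no code with the package's selection path.  The
numerical conventions that define the method (variance floor from the full
training matrix, ties to the lower class code, score ties to the lowest gene
index) are reproduced from their definitions.
"""

import math

import numpy as np


def floor_from(X):
    X = np.asarray(X, dtype=float)
    return max(1e-9 * float(np.mean(np.var(X, axis=0))), 1e-12)


class OracleNB:
    def __init__(self, X, y, floor):
        self.classes = sorted(set(int(c) for c in y))
        self.params = {}
        n = len(y)
        for c in self.classes:
            Xc = X[np.asarray(y) == c]
            mu = Xc.mean(axis=0)
            var = np.maximum(Xc.var(axis=0), floor)
            self.params[c] = (math.log(len(Xc) / n), mu, var)

    def predict_one(self, x):
        best_c, best_score = None, None
        for c in self.classes:
            logp, mu, var = self.params[c]
            score = logp
            for f in range(len(x)):
                score += -0.5 * (math.log(2 * math.pi * var[f])
                                 + (x[f] - mu[f]) ** 2 / var[f])
            if best_score is None or score > best_score:
                best_c, best_score = c, score
        return best_c


class OracleNMS:
    def __init__(self, X, y, floor):
        y = np.asarray(y)
        self.classes = sorted(set(int(c) for c in y))
        self.means = {c: X[y == c].mean(axis=0) for c in self.classes}
        ss = np.zeros(X.shape[1])
        for c in self.classes:
            ss += ((X[y == c] - self.means[c]) ** 2).sum(axis=0)
        self.pooled = np.maximum(ss / max(len(y) - len(self.classes), 1), floor)

    def predict_one(self, x):
        best_c, best_d = None, None
        for c in self.classes:
            d = 0.0
            for f in range(len(x)):
                d += (x[f] - self.means[c][f]) ** 2 / self.pooled[f]
            if best_d is None or d < best_d:
                best_c, best_d = c, d
        return best_c


def fit(name, X, y, floor):
    return OracleNB(X, y, floor) if name == "nbc" else OracleNMS(X, y, floor)


def accuracy_count(name, X, y, mode, floor):
    """Correct-prediction count by explicit refits (loo) or one fit (resub)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    correct = 0
    if mode == "resub":
        model = fit(name, X, y, floor)
        for j in range(n):
            correct += int(model.predict_one(X[j]) == y[j])
        return correct
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        model = fit(name, X[keep], y[keep], floor)
        correct += int(model.predict_one(X[j]) == y[j])
    return correct


def cor2(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.std(u) == 0.0 or np.std(v) == 0.0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1] ** 2)


def brute_rfa(genes_by_samples, y, p_values, name, mode, criterion, max_dim):
    """Forward selection by exhaustive scan; returns (chosen, correct_counts)."""
    G = np.asarray(genes_by_samples, dtype=float)
    X = G.T
    floor = floor_from(X)
    n_genes = G.shape[0]
    counts = [accuracy_count(name, X[:, [g]], y, mode, floor) for g in range(n_genes)]
    best = max(counts)
    tied = [g for g in range(n_genes) if counts[g] == best]
    tied.sort(key=lambda g: (p_values[g], g))
    chosen = [tied[0]]
    accs = [best]
    while len(chosen) < max_dim:
        unchosen = [g for g in range(n_genes) if g not in chosen]
        counts = {g: accuracy_count(name, X[:, chosen + [g]], y, mode, floor)
                  for g in unchosen}
        best = max(counts.values())
        cand = [g for g in unchosen if counts[g] == best]
        if len(cand) == 1:
            pick = cand[0]
        else:
            scores = {}
            for g in cand:
                c2 = [cor2(G[g], G[h]) for h in chosen]
                scores[g] = sum(c2) if criterion == "msc" else max(c2)
            pick = min(cand, key=lambda g: (scores[g], g))
        chosen.append(pick)
        accs.append(best)
    return chosen, accs
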