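"""Independent explicit-loop reference implementations.

These deliberately use plain Python loops and the printed formulas only —
no code shared with the package — so they can serve as oracles for the
vectorized implementations.
"""

import numpy as np


def ncc_loops(a, b):
    X, Y, Z = a.shape
    mu_a = a.mean()
    mu_b = b.mean()
    num = 0.0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                num += (a[x, y, z] - mu_a) * (b[x, y, z] - mu_b)
    return num / (X * Y * Z * np.sqrt(a.var() * b.var()))


def lncc_loops(fixed, warped, n, eps):
    X, Y, Z = fixed.shape
    total = 0.0
    count = 0
    for x in range(X - n + 1):
        for y in range(Y - n + 1):
            for z in range(Z - n + 1):
                f = fixed[x : x + n, y : y + n, z : z + n]
                p = warped[x : x + n, y : y + n, z : z + n]
                ef, ep = f.mean(), p.mean()
                efp = (f * p).mean()
                vf = (f * f).mean() - ef * ef
                vp = (p * p).mean() - ep * ep
                total += (efp - ef * ep) ** 2 / (max(vf, 0) * max(vp, 0) + eps)
                count += 1
    return -total / count


def centroid_loss_loops(y_true, y_pred):
    dists = []
    for row_t, row_p in zip(y_true, y_pred):
        if tuple(row_t) == (-1.0, -1.0, -1.0) or tuple(row_p) == (-1.0, -1.0, -1.0):
            continue
        dists.append(
            np.sqrt(sum((row_t[d] - row_p[d]) ** 2 for d in range(3)))
        )
    return sum(dists) / len(dists)


def gradient_norm_loops(d):
    X, Y, Z, _ = d.shape
    total = 0.0
    for i in range(1, X - 1):
        for j in range(1, Y - 1):
            for k in range(1, Z - 1):
                for m in range(3):
                    dx = 0.5 * (d[i + 1, j, k, m] - d[i - 1, j, k, m])
                    dy = 0.5 * (d[i, j + 1, k, m] - d[i, j - 1, k, m])
                    dz = 0.5 * (d[i, j, k + 1, m] - d[i, j, k - 1, m])
                    total += dx * dx + dy * dy + dz * dz
    return total / (3 * (X - 2) * (Y - 2) * (Z - 2))


def gradient_norm_2d_loops(d):
    X, Y, Z, _ = d.shape
    total = 0.0
    for i in range(1, X - 1):
        for j in range(1, Y - 1):
            for k in range(Z):
                for m in range(3):
                    dx = 0.5 * (d[i + 1, j, k, m] - d[i - 1, j, k, m])
                    dy = 0.5 * (d[i, j + 1, k, m] - d[i, j - 1, k, m])
                    total += dx * dx + dy * dy
    return total / (3 * (X - 2) * (Y - 2) * Z)


def difference_norm_loops(d):
    X, Y, Z, _ = d.shape
    total = 0.0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                for m in range(3):
                    total += d[i, j, k, m] ** 2
    return total / (3 * X * Y * Z)


def axis_difference_norm_loops(d):
    X, Y, Z, _ = d.shape
    total = 0.0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                total += d[i, j, k, 2] ** 2
    return total / (X * Y * Z)


def nonrigid_penalty_loops(d, floor=1e-8):
    X, Y, Z, _ = d.shape
    diff = d.copy()
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                diff[i, j, k] += (i, j, k)  # D - D_ref with D_ref = (-x, -y, -z)
    total = 0.0
    for i in range(1, X - 1):
        for j in range(1, Y - 1):
            for k in range(1, Z - 1):
                for m in range(3):
                    dx = 0.5 * (diff[i + 1, j, k, m] - diff[i - 1, j, k, m])
                    dy = 0.5 * (diff[i, j + 1, k, m] - diff[i, j - 1, k, m])
                    dz = 0.5 * (diff[i, j, k + 1, m] - diff[i, j, k - 1, m])
                    mval = max(dx * dx + dy * dy + dz * dz, floor)
                    total += abs(mval + 1.0 / mval - 2.0)
    return total / (3 * (X - 2) * (Y - 2) * (Z - 2))


def multichannel_ncc_loss_loops(fixed, warped):
    C = fixed.shape[3]
    total = 0.0
    for c in range(C):
        total += ncc_loops(fixed[..., c], warped[..., c]) ** 2
    return -total / C


def weighted_cross_entropy_loops(logits, target, weights):
    K, X, Y, Z = logits.shape
    total = 0.0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                col = logits[:, x, y, z]
                logsumexp = np.log(np.exp(col - col.max()).sum()) + col.max()
                for n in range(K):
                    total += (
                        weights[x, y, z]
                        * target[n, x, y, z]
                        * (col[n] - logsumexp)
                    )
    return -total / (K * X * Y * Z)


def weighted_mean_iou_loops(probabilities, target, weights):
    K, X, Y, Z = probabilities.shape
    scores = []
    for n in range(K):
        inter = 0.0
        union = 0.0
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    a = 1.0 if probabilities[:, x, y, z].argmax() == n else 0.0
                    l = target[n, x, y, z]
                    inter += weights[x, y, z] * l * a
                    union += weights[x, y, z] * max(l, a)
        scores.append(inter / union if union > 0 else 1.0)
    return float(np.mean(scores))
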