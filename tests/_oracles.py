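"""Brute-force reference implementations used as test oracles.

Everything here is written as literally as possible — loops, textbook
formulas, no shared code with the package — so agreement between the
package and these functions is meaningful.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# hill-climb clustering oracle
# ---------------------------------------------------------------------------

def hill_climb_labels(response, mask, radius):
    """Naive repeated hill-climbing: from every pixel, step to the best
    (response, smallest-linear-index) pixel in its Euclidean disk until a
    fixed point is reached.  Labels are numbered in row-major order of
    the fixed points."""
    response = np.asarray(response, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = response.shape
    r_int = int(math.floor(radius))
    offsets = [
        (dr, dc)
        for dr in range(-r_int, r_int + 1)
        for dc in range(-r_int, r_int + 1)
        if dr * dr + dc * dc <= radius * radius
    ]

    def best_neighbor(r, c):
        best = (response[r, c], r * w + c)
        best_rc = (r, c)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                cand = (response[rr, cc], rr * w + cc)
                # larger response wins; ties broken by smaller index
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
                    best_rc = (rr, cc)
        return best_rc

    final = {}
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            cur = (r, c)
            for _ in range(h * w + 1):
                nxt = best_neighbor(*cur)
                if nxt == cur:
                    break
                cur = nxt
            final[(r, c)] = cur

    roots = sorted({p for p in final.values()}, key=lambda p: p[0] * w + p[1])
    root_label = {p: i for i, p in enumerate(roots, start=1)}
    labels = np.zeros((h, w), dtype=np.int32)
    for (r, c), root in final.items():
        labels[r, c] = root_label[root]
    return labels


# ---------------------------------------------------------------------------
# intensity / gradient statistics oracles
# ---------------------------------------------------------------------------

def intensity_stats(values):
    """The 12 intensity statistics recomputed from their definitions."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    median = float(np.median(v))
    m2 = sum((x - mean) ** 2 for x in v) / n
    std = math.sqrt(m2)
    if m2 > 0:
        skew = (sum((x - mean) ** 3 for x in v) / n) / m2**1.5
        kurt = (sum((x - mean) ** 4 for x in v) / n) / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    q75, q25 = np.percentile(v, [75, 25])
    mad = float(np.median([abs(x - median) for x in v]))
    entropy, energy = histogram_entropy_energy(v, 10)
    return {
        "Intensity.Min": v[0],
        "Intensity.Max": v[-1],
        "Intensity.Mean": mean,
        "Intensity.Median": median,
        "Intensity.MeanMedianDiff": mean - median,
        "Intensity.Std": std,
        "Intensity.IQR": float(q75 - q25),
        "Intensity.MAD": mad,
        "Intensity.Skewness": skew,
        "Intensity.Kurtosis": kurt,
        "Intensity.HistEntropy": entropy,
        "Intensity.HistEnergy": energy,
    }


def histogram_entropy_energy(values, bins):
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return 0.0, 1.0
    counts, _ = np.histogram(v, bins=bins, range=(lo, hi))
    p = counts / counts.sum()
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    energy = sum(pi * pi for pi in p)
    return float(entropy), float(energy)


# ---------------------------------------------------------------------------
# Haralick oracle (literal textbook formulas on an explicit GLCM)
# ---------------------------------------------------------------------------

def glcm_counts(mask, quantized, levels, offset):
    """Symmetric co-occurrence counts accumulated pixel by pixel."""
    h, w = mask.shape
    dr, dc = offset
    glcm = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                a, b = quantized[r, c], quantized[rr, cc]
                glcm[a, b] += 1
                glcm[b, a] += 1
    return glcm


def haralick_13(p):
    """Haralick's 13 features of a normalized symmetric GLCM, log base 2."""
    levels = p.shape[0]
    px = [sum(p[i, j] for j in range(levels)) for i in range(levels)]
    py = [sum(p[i, j] for i in range(levels)) for j in range(levels)]
    mx = sum(i * px[i] for i in range(levels))
    my = sum(j * py[j] for j in range(levels))
    vx = sum((i - mx) ** 2 * px[i] for i in range(levels))
    vy = sum((j - my) ** 2 * py[j] for j in range(levels))

    asm = sum(p[i, j] ** 2 for i in range(levels) for j in range(levels))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    if vx > 0 and vy > 0:
        corr = (sum(i * j * p[i, j] for i in range(levels) for j in range(levels))
                - mx * my) / math.sqrt(vx * vy)
    else:
        corr = 0.0
    variance = sum((i - mx) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(levels) for j in range(levels))

    psum = [0.0] * (2 * levels - 1)
    pdiff = [0.0] * levels
    for i in range(levels):
        for j in range(levels):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]

    sum_avg = sum(k * psum[k] for k in range(len(psum)))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(len(psum)))
    sum_ent = -sum(q * math.log2(q) for q in psum if q > 0)
    mu_diff = sum(k * pdiff[k] for k in range(levels))
    diff_var = sum((k - mu_diff) ** 2 * pdiff[k] for k in range(levels))
    diff_ent = -sum(q * math.log2(q) for q in pdiff if q > 0)

    hxy = -sum(p[i, j] * math.log2(p[i, j])
               for i in range(levels) for j in range(levels) if p[i, j] > 0)
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hy = -sum(q * math.log2(q) for q in py if q > 0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(levels) for j in range(levels)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(levels) for j in range(levels)
                if px[i] * py[j] > 0)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0))

    return {
        "Haralick.ASM": asm,
        "Haralick.Contrast": contrast,
        "Haralick.Correlation": corr,
        "Haralick.SumOfSquares": variance,
        "Haralick.IDM": idm,
        "Haralick.SumAverage": sum_avg,
        "Haralick.SumVariance": sum_var,
        "Haralick.SumEntropy": sum_ent,
        "Haralick.Entropy": hxy,
        "Haralick.DifferenceVariance": diff_var,
        "Haralick.DifferenceEntropy": diff_ent,
        "Haralick.IMC1": imc1,
        "Haralick.IMC2": imc2,
    }


def quantize_minmax(values, levels):
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=int)
    q = ((values - lo) / (hi - lo) * levels).astype(int)
    return np.minimum(q, levels - 1)


# ---------------------------------------------------------------------------
# Prim's MST oracle
# ---------------------------------------------------------------------------

def prim_mst_length(points):
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    in_tree = [False] * n
    dist = [math.inf] * n
    dist[0] = 0.0
    total = 0.0
    for _ in range(n):
        u = min((d, i) for i, d in enumerate(dist) if not in_tree[i])[1]
        in_tree[u] = True
        total += dist[u]
        for v in range(n):
            if not in_tree[v]:
                d = math.hypot(pts[u, 0] - pts[v, 0], pts[u, 1] - pts[v, 1])
                if d < dist[v]:
                    dist[v] = d
    return total


# ---------------------------------------------------------------------------
# positive-pixel-count oracle (literal per-pixel rule)
# ---------------------------------------------------------------------------

def ppc_counts(im_rgb, params):
    """Classify every pixel with scalar arithmetic; returns count dict."""
    im = np.asarray(im_rgb, dtype=float)
    h, w, _ = im.shape
    counts = {"negative": 0, "weak": 0, "plain": 0, "strong": 0}
    for r in range(h):
        for c in range(w):
            red, g, b = im[r, c]
            inten = (red + g + b) / 3.0
            mn = min(red, g, b)
            sat = 1.0 - mn / inten if inten > 0 else 0.0
            num = 0.5 * ((red - g) + (red - b))
            den = math.sqrt((red - g) ** 2 + (red - b) * (g - b))
            if den < 1e-12:
                hue = 0.0
            else:
                theta = math.acos(max(-1.0, min(1.0, num / max(den, 1e-12))))
                hue = (2 * math.pi - theta) if b > g else theta
                hue = (hue / (2 * math.pi)) % 1.0
            d = abs(hue - params.hue_value)
            d = min(d, 1.0 - d)
            positive = (
                d <= params.hue_width / 2.0
                and sat >= params.saturation_minimum
                and params.intensity_lower_limit <= inten < params.intensity_upper_limit
            )
            if not positive:
                counts["negative"] += 1
            elif inten < params.intensity_strong_threshold:
                counts["strong"] += 1
            elif inten < params.intensity_weak_threshold:
                counts["plain"] += 1
            else:
                counts["weak"] += 1
    return counts


# ---------------------------------------------------------------------------
# confusion-matrix metrics oracle
# ---------------------------------------------------------------------------

def confusion_metrics(pred, truth):
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    return precision, recall, accuracy, f1, iou


# ---------------------------------------------------------------------------
# centroid matching helper
# ---------------------------------------------------------------------------

def match_centroids(detected, truth):
    """Greedy one-to-one matching; returns per-truth distances (inf if
    unmatched)."""
    detected = [tuple(p) for p in np.asarray(detected, dtype=float).reshape(-1, 2)]
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    dists = []
    used = set()
    for t in truth:
        best, best_i = math.inf, None
        for i, d in enumerate(detected):
            if i in used:
                continue
            dd = math.hypot(t[0] - d[0], t[1] - d[1])
            if dd < best:
                best, best_i = dd, i
        if best_i is not None:
            used.add(best_i)
        dists.append(best)
    return np.array(dists)
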