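"""Independent brute-force oracles for the texture machinery.

Everything here is written as plainly as possible (explicit loops, direct
formula transcription) and shares no code with the package implementation,
so agreement between the two routes is meaningful.
"""

import math

import numpy as np

OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def oracle_wiener(image, kernel=3):
    """Direct windowed computation of the adaptive Wiener formula."""
    x = np.asarray(image, dtype=float)
    k = kernel // 2
    pad = np.pad(x, k, mode="symmetric")
    h, w = x.shape
    means = np.zeros_like(x)
    varis = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            win = pad[i:i + kernel, j:j + kernel]
            means[i, j] = win.mean()
            varis[i, j] = win.var()
    nu = varis.mean()
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            v = varis[i, j]
            denom = max(v, nu)
            gain = max(v - nu, 0.0) / denom if denom > 0 else 0.0
            out[i, j] = means[i, j] + gain * (x[i, j] - means[i, j])
    return out


def oracle_glcm(labels):
    """All in-mask distance-1 pixel pairs, 4 directions, symmetrized."""
    lab = np.asarray(labels)
    ng = int(lab.max())
    glcm = np.zeros((ng, ng))
    h, w = lab.shape
    for dr, dc in OFFSETS:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and lab[r, c] > 0 and lab[r2, c2] > 0:
                    glcm[lab[r, c] - 1, lab[r2, c2] - 1] += 1
                    glcm[lab[r2, c2] - 1, lab[r, c] - 1] += 1
    return glcm


def oracle_glrlm(labels):
    """Maximal runs per direction by explicit walking."""
    lab = np.asarray(labels)
    ng = int(lab.max())
    h, w = lab.shape
    runs = []
    for dr, dc in OFFSETS:
        for r in range(h):
            for c in range(w):
                v = lab[r, c]
                if v <= 0:
                    continue
                pr, pc = r - dr, c - dc
                if 0 <= pr < h and 0 <= pc < w and lab[pr, pc] == v:
                    continue  # not a run start
                length = 0
                rr, cc = r, c
                while 0 <= rr < h and 0 <= cc < w and lab[rr, cc] == v:
                    length += 1
                    rr, cc = rr + dr, cc + dc
                runs.append((v, length))
    max_len = max((l for _, l in runs), default=1)
    m = np.zeros((ng, max_len))
    for v, l in runs:
        m[v - 1, l - 1] += 1
    return m


def oracle_glszm(labels):
    """8-connected constant-label zones by flood fill."""
    lab = np.asarray(labels)
    ng = int(lab.max())
    h, w = lab.shape
    seen = np.zeros_like(lab, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if lab[r, c] <= 0 or seen[r, c]:
                continue
            v = lab[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                                and lab[r2, c2] == v):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((v, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((ng, max_size))
    for v, s in zones:
        m[v - 1, s - 1] += 1
    return m


def _log2(x):
    return math.log2(x)


def oracle_glcm_features(glcm):
    """Naive loop transcription of the co-occurrence feature formulas."""
    p = glcm / glcm.sum()
    ng = p.shape[0]
    f = {}
    f["F_cm.joint.max"] = p.max()
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f["F_cm.joint.avg"] = mu
    f["F_cm.joint.var"] = sum((i + 1 - mu) ** 2 * p[i, j]
                              for i in range(ng) for j in range(ng))
    f["F_cm.joint.entr"] = -sum(p[i, j] * _log2(p[i, j])
                                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    pxmy = [sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
            for k in range(ng)]
    da = sum(k * pxmy[k] for k in range(ng))
    f["F_cm.diff.avg"] = da
    f["F_cm.diff.var"] = sum((k - da) ** 2 * pxmy[k] for k in range(ng))
    f["F_cm.diff.entr"] = -sum(q * _log2(q) for q in pxmy if q > 0)
    pxpy = {k: sum(p[i, j] for i in range(ng) for j in range(ng)
                   if (i + 1) + (j + 1) == k) for k in range(2, 2 * ng + 1)}
    sa = sum(k * q for k, q in pxpy.items())
    f["F_cm.sum.avg"] = sa
    f["F_cm.sum.var"] = sum((k - sa) ** 2 * q for k, q in pxpy.items())
    f["F_cm.sum.entr"] = -sum(q * _log2(q) for q in pxpy.values() if q > 0)
    f["F_cm.energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["F_cm.contrast"] = sum((i - j) ** 2 * p[i, j]
                             for i in range(ng) for j in range(ng))
    f["F_cm.dissimilarity"] = sum(abs(i - j) * p[i, j]
                                  for i in range(ng) for j in range(ng))
    f["F_cm.inv.diff"] = sum(p[i, j] / (1 + abs(i - j))
                             for i in range(ng) for j in range(ng))
    f["F_cm.inv.diff.norm"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                                  for i in range(ng) for j in range(ng))
    f["F_cm.inv.diff.mom"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                 for i in range(ng) for j in range(ng))
    f["F_cm.inv.diff.mom.norm"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng ** 2)
                                      for i in range(ng) for j in range(ng))
    f["F_cm.inv.var"] = sum(p[i, j] / (i - j) ** 2
                            for i in range(ng) for j in range(ng) if i != j)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    sig = math.sqrt(sum((i + 1 - mu) ** 2 * px[i] for i in range(ng)))
    if sig > 0:
        f["F_cm.corr"] = sum((i + 1 - mu) * (j + 1 - mu) * p[i, j]
                             for i in range(ng) for j in range(ng)) / sig ** 2
    else:
        f["F_cm.corr"] = 1.0
    f["F_cm.auto.corr"] = sum((i + 1) * (j + 1) * p[i, j]
                              for i in range(ng) for j in range(ng))
    for power, name in ((2, "F_cm.clust.tend"), (3, "F_cm.clust.shade"),
                        (4, "F_cm.clust.prom")):
        f[name] = sum(((i + 1) + (j + 1) - 2 * mu) ** power * p[i, j]
                      for i in range(ng) for j in range(ng))
    hxy = f["F_cm.joint.entr"]
    hx = -sum(q * _log2(q) for q in px if q > 0)
    hxy1 = -sum(p[i, j] * _log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * px[j] * _log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    f["F_cm.info.corr.1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["F_cm.info.corr.2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    return f


def oracle_rl_features(m, prefix, n_pixels, n_directions=None):
    """Naive run-length / size-zone feature formulas.

    ``prefix`` is "F_rlm" or "F_szm"; name suffixes follow the registry.
    """
    total = m.sum()
    p = m / total
    ng, nl = p.shape
    f = {}
    sfx = {
        "F_rlm": dict(short="sre", long="lre", low="lgre", high="hgre",
                      sl="srlge", sh="srhge", ll="lrlge", lh="lrhge",
                      gn="glnu", gnn="glnu.norm", ln="rlnu", lnn="rlnu.norm",
                      perc="r.perc", gv="gl.var", lv="rl.var", ent="rl.entr"),
        "F_szm": dict(short="sze", long="lze", low="lgze", high="hgze",
                      sl="szlge", sh="szhge", ll="lzlge", lh="lzhge",
                      gn="glu", gnn="glu.norm", ln="zsnu", lnn="zsnu.norm",
                      perc="z.perc", gv="gl.var", lv="zs.var", ent="zs.entr"),
    }[prefix]

    def nm(k):
        return f"{prefix}.{sfx[k]}"

    f[nm("short")] = sum(p[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f[nm("long")] = sum(p[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f[nm("low")] = sum(p[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f[nm("high")] = sum(p[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f[nm("sl")] = sum(p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                      for i in range(ng) for j in range(nl))
    f[nm("sh")] = sum(p[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                      for i in range(ng) for j in range(nl))
    f[nm("ll")] = sum(p[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                      for i in range(ng) for j in range(nl))
    f[nm("lh")] = sum(p[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                      for i in range(ng) for j in range(nl))
    f[nm("gn")] = sum(m[i, :].sum() ** 2 for i in range(ng)) / total
    f[nm("gnn")] = sum(m[i, :].sum() ** 2 for i in range(ng)) / total ** 2
    f[nm("ln")] = sum(m[:, j].sum() ** 2 for j in range(nl)) / total
    f[nm("lnn")] = sum(m[:, j].sum() ** 2 for j in range(nl)) / total ** 2
    denom = n_pixels * (n_directions if n_directions else 1)
    f[nm("perc")] = total / denom
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nl))
    f[nm("gv")] = sum((i + 1 - mu_i) ** 2 * p[i, j]
                      for i in range(ng) for j in range(nl))
    f[nm("lv")] = sum((j + 1 - mu_j) ** 2 * p[i, j]
                      for i in range(ng) for j in range(nl))
    f[nm("ent")] = -sum(p[i, j] * _log2(p[i, j])
                        for i in range(ng) for j in range(nl) if p[i, j] > 0)
    return f


def oracle_all_texture_features(labels):
    """All 57 texture features of a label grid via the brute-force route."""
    lab = np.asarray(labels)
    n_pixels = int((lab > 0).sum())
    out = oracle_glcm_features(oracle_glcm(lab))
    out.update(oracle_rl_features(oracle_glrlm(lab), "F_rlm", n_pixels,
                                  n_directions=4))
    out.update(oracle_rl_features(oracle_glszm(lab), "F_szm", n_pixels))
    return out
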