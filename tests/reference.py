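"""Independent straight-line reference implementations of every transform.

These are deliberately written with explicit Python loops and share no code
with the package.  They consume random draws from the supplied generator in
the same documented order as the library (selection mask first, then
permutation; blocks/regions in row-major / label order), so given the same
seed they must reproduce the library's output bit-for-bit on small images.
"""

import numpy as np


def ref_full_random_shuffle(img, p, rng):
    h, w, _ = img.shape
    u = rng.random((h, w))
    selected = []
    for r in range(h):
        for c in range(w):
            if u[r, c] < p:
                selected.append((r, c))
    perm = rng.permutation(len(selected))
    out = img.copy()
    for t in range(len(selected)):
        tr, tc = selected[t]
        sr, sc = selected[int(perm[t])]
        out[tr, tc] = img[sr, sc]
    return out


def ref_selected_count(img_shape, p, rng):
    """Number of Bernoulli-selected pixel locations for one seeded draw."""
    h, w = img_shape
    u = rng.random((h, w))
    count = 0
    for r in range(h):
        for c in range(w):
            if u[r, c] < p:
                count += 1
    return count


def ref_grid_shuffle(img, b, rng):
    h, w, _ = img.shape
    rows, cols = h // b, w // b
    perm = rng.permutation(rows * cols)
    out = img.copy()
    for t in range(rows * cols):
        tr, tc = divmod(t, cols)
        sr, sc = divmod(int(perm[t]), cols)
        out[tr * b:(tr + 1) * b, tc * b:(tc + 1) * b] = \
            img[sr * b:(sr + 1) * b, sc * b:(sc + 1) * b]
    return out


def ref_within_grid_shuffle(img, b, p, rng):
    h, w, _ = img.shape
    out = img.copy()
    for r0 in range(0, h, b):
        for c0 in range(0, w, b):
            block = img[r0:r0 + b, c0:c0 + b]
            out[r0:r0 + b, c0:c0 + b] = ref_full_random_shuffle(block, p, rng)
    return out


def ref_local_structure_shuffle(img, b, p, rng):
    return ref_grid_shuffle(ref_within_grid_shuffle(img, b, p, rng), b, rng)


def ref_color_flatten(img):
    h, w, _ = img.shape
    red, green, blue = [], [], []
    for r in range(h):
        for c in range(w):
            red.append(img[r, c, 0])
            green.append(img[r, c, 1])
            blue.append(img[r, c, 2])
    return np.array(red), np.array(green), np.array(blue)


def ref_segmentation_within_shuffle(img, labels, p, rng):
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    lab = labels.ravel()
    out = flat.copy()
    for region in range(int(labels.max()) + 1):
        locs = [i for i in range(h * w) if lab[i] == region]
        u = rng.random(len(locs))
        sel = [locs[i] for i in range(len(locs)) if u[i] < p]
        perm = rng.permutation(len(sel))
        vals = [flat[sel[int(perm[t])]].copy() for t in range(len(sel))]
        for t, loc in enumerate(sel):
            out[loc] = vals[t]
    return out.reshape(img.shape)


def ref_region_transfer(source, target_size, rng):
    source = [np.array(px) for px in source]
    m = len(source)
    if target_size > m:
        extra = rng.integers(0, m, size=target_size - m)
        pool = source + [source[int(i)] for i in extra]
    else:
        pool = source
    perm = rng.permutation(len(pool))
    return [pool[int(perm[t])] for t in range(target_size)]


def ref_segmentation_displacement_shuffle(img, labels, rng):
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    lab = labels.ravel()
    k = int(labels.max()) + 1
    out = flat.copy()
    destination = rng.permutation(k)
    for source_region in range(k):
        dest_region = int(destination[source_region])
        src_locs = [i for i in range(h * w) if lab[i] == source_region]
        dest_locs = [i for i in range(h * w) if lab[i] == dest_region]
        transferred = ref_region_transfer([flat[i] for i in src_locs],
                                          len(dest_locs), rng)
        for t, loc in enumerate(dest_locs):
            out[loc] = transferred[t]
    return out.reshape(img.shape)
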