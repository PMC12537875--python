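"""Independent brute-force oracles shared by the heavier end-to-end tests.

These deliberately avoid the package's own algorithms: the motif oracle
enumerates all position triples, and the count oracle loops over all nine
lateral periodic images.
"""

import itertools

import numpy as np


def brute_force_triples(sequence, pattern):
    """All (p1, p2, p3) anchor triples via exhaustive combination testing."""
    a1, a2, a3 = pattern.anchors
    hits = []
    for p1, p2, p3 in itertools.combinations(range(1, len(sequence) + 1), 3):
        if (sequence[p1 - 1] in a1 and sequence[p2 - 1] in a2
                and sequence[p3 - 1] in a3
                and 1 <= p2 - p1 - 1 <= 5 and 1 <= p3 - p2 - 1 <= 5):
            hits.append((p1, p2, p3))
    return sorted(hits)


def nine_image_counts(frame, r):
    """(chol, popc) lateral counts testing all 9 periodic images per point."""
    out = []
    for points in (frame.chol_points, frame.popc_points):
        n = 0
        for p in points:
            best = np.inf
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    shifted = p[:2] + np.array([ix, iy]) * frame.box[:2]
                    best = min(best,
                               np.hypot(*(shifted - frame.peptide_com[:2])))
            if best <= r:
                n += 1
        out.append(n)
    return out
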