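"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-Python loops, explicit minimum
image) kept separate from the package so the tests compare two independent
code paths.
"""

import math

import numpy as np


def mi_distance(a, b, box):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= box * np.round(d / box)
    return math.sqrt(float(np.dot(d, d)))


def mi_vec(a, b, box):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return d - box * np.round(d / box)


def angle_deg(v1, v2):
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def brute_force_hbond_count(snapshot, donors, hydrogens, acceptors,
                            max_dist, max_dev, vertex):
    """O(n^2) recount of geometric hydrogen bonds."""
    count = 0
    pos = snapshot.positions
    box = snapshot.box
    for d in donors:
        for a in acceptors:
            if int(d) == int(a):
                continue
            if mi_distance(pos[d], pos[a], box) > max_dist:
                continue
            for h in hydrogens[int(d)]:
                if vertex == "hydrogen":
                    dev = 180.0 - angle_deg(
                        mi_vec(pos[d], pos[h], box), mi_vec(pos[a], pos[h], box)
                    )
                else:
                    dev = angle_deg(
                        mi_vec(pos[h], pos[d], box), mi_vec(pos[a], pos[d], box)
                    )
                if dev <= max_dev:
                    count += 1
    return count


def brute_force_close_pairs(snapshot, residue_id, cutoff):
    """All intra-residue pairs within cutoff, as a set of (i, j) with i < j."""
    idx = [int(i) for i in np.flatnonzero(snapshot.resids == residue_id)]
    pairs = set()
    for n, i in enumerate(idx):
        for j in idx[n + 1:]:
            if mi_distance(snapshot.positions[i], snapshot.positions[j], snapshot.box) <= cutoff:
                pairs.add((min(i, j), max(i, j)))
    return pairs
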