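"""Independent interior-path-length oracle for closed meshes.

Deliberately a different algorithm from the production L-buffer: each
triangle is intersected via its supporting-plane equation plus edge-function
sign tests (not Moeller-Trumbore), and the interior length comes from
parity-pairing the sorted hit distances (not from a signed accumulation).
Python-slow but trustworthy; used only to cross-check the fast kernel.
"""

import numpy as np


def interval_path_length(origin, direction, mesh) -> float:
    """Chord length (cm) of a ray inside a watertight mesh, by hit pairing."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tri = mesh.triangles.view(np.ndarray)
    n = mesh.face_normals.view(np.ndarray)

    denom = n @ d
    ok = np.abs(denom) > 1e-12
    t = np.einsum("ij,ij->i", n, tri[:, 0] - o[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t / denom
    pts = o[None, :] + t[:, None] * d[None, :]

    inside = ok & (t > 1e-9)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        edge = tri[:, b] - tri[:, a]
        to_pt = pts - tri[:, a]
        side = np.einsum("ij,ij->i", np.cross(edge, to_pt), n)
        inside &= side >= -1e-9
    ts = np.sort(t[inside])
    if ts.size == 0:
        return 0.0
    if ts.size % 2 == 1:  # origin is interior: segment [0, ts[0]] counts
        ts = np.concatenate([[0.0], ts])
    return float(np.sum(ts[1::2] - ts[0::2])) / 10.0
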