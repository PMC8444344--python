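"""AO->MO transformations via reshaped matrix products."""

from __future__ import annotations

import numpy as np


def transform_eri(eri_ao: np.ndarray, c1, c2=None, c3=None, c4=None) -> np.ndarray:
    """(pq|rs) -> (ij|kl) with independent coefficient matrices per index.

    Chemists' notation is preserved: index 1,2 on electron one, 3,4 on
    electron two.  Any of c2..c4 default to c1.  Indices are contracted
    narrowest-first, which makes partial-block transforms (a few columns on
    some indices) cheap.
    """
    c2 = c1 if c2 is None else c2
    c3 = c1 if c3 is None else c3
    c4 = c1 if c4 is None else c4
    cs = [c1, c2, c3, c4]
    x = eri_ao
    pos = {i: i for i in range(4)}     # axis position of untransformed indices
    newpos = {}                        # axis position of transformed indices
    for k in sorted(range(4), key=lambda i: cs[i].shape[1]):
        ax = pos.pop(k)
        x = np.tensordot(x, cs[k], axes=([ax], [0]))  # new axis appended last
        for d in pos:
            if pos[d] > ax:
                pos[d] -= 1
        for d in newpos:
            if newpos[d] > ax:
                newpos[d] -= 1
        newpos[k] = x.ndim - 1
    return np.ascontiguousarray(np.transpose(x, [newpos[i] for i in range(4)]))


def transform_matrix(m_ao: np.ndarray, c1, c2=None) -> np.ndarray:
    c2 = c1 if c2 is None else c2
    return c1.T @ m_ao @ c2
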