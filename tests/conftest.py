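import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import foldpath as fp
from foldpath import synthetic as syn


@pytest.fixture
def helix40():
    return syn.make_helix(40)


@pytest.fixture
def manifest():
    return fp.load_cotranslational_manifest()


def rigid_move(conf, seed):
    """Apply a random proper rigid motion to a conformation's Cα trace."""
    import dataclasses
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng)
    t = rng.uniform(-30, 30, 3)
    coords = R.apply(conf.coords) + t
    return dataclasses.replace(
        conf,
        residues=[dataclasses.replace(r, ca=c)
                  for r, c in zip(conf.residues, coords)],
    )


def conf_from_coords(coords, protein_id="x", **kw):
    from foldpath.structures import Conformation, Residue
    residues = [Residue(seq_index=i + 1, aa="A", ca=c)
                for i, c in enumerate(np.asarray(coords, dtype=float))]
    return Conformation(protein_id=protein_id, residues=residues, **kw)
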