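"""Proxy co-translational intermediates.

A "proxy" intermediate is the prefix substructure of a native structure:
the first k residues (and their native coordinates), then the first 2k,
3k, ... until the full chain.  The default k = 5 mimics the addition of
individual secondary-structure elements during translation.  Proxies are
deliberately naive: they are cut from the same static native structure
and carry no conformational change, which is exactly what makes them a
large-scale stand-in for real co-translational intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .structures import Conformation, Pathway

__all__ = ["ProxySchedule", "proxy_schedule", "generate_proxy_intermediates",
           "match_proxy", "DEFAULT_K"]

DEFAULT_K = 5


@dataclass
class ProxySchedule:
    """Prefix lengths k, 2k, ... with the last entry equal to the full
    chain length L (no short remainder-only intermediate)."""

    k: int
    L: int
    prefix_lengths: list[int]


def proxy_schedule(L: int, k: int = DEFAULT_K) -> ProxySchedule:
    if L < 1 or k < 1:
        raise ValueError("L and k must be >= 1")
    lengths = list(range(k, L + 1, k))
    if not lengths or lengths[-1] != L:
        lengths.append(L)
    return ProxySchedule(k=k, L=L, prefix_lengths=lengths)


def generate_proxy_intermediates(native: Conformation, k: int = DEFAULT_K) -> Pathway:
    """Cut the native structure into its proxy-intermediate pathway.

    Prefixes are taken over modeled residues in order (not author-number
    arithmetic), so natives with unmodeled gaps still yield well-formed
    proxies.  Coordinates are shared with the native — no re-modelling.
    """
    if len(native) < 1:
        raise ValueError("native conformation has no residues")
    sched = proxy_schedule(len(native), k)
    intermediates = []
    for t, n in enumerate(sched.prefix_lengths):
        conf = native.subset(range(n))
        conf = replace(conf, intermediate_index=t,
                       is_native=(n == sched.L and native.is_native))
        intermediates.append((t, [conf]))
    return Pathway(protein_id=native.protein_id, intermediates=intermediates)


def match_proxy(proxies: Pathway, target: Conformation) -> Conformation:
    """Proxy whose residue count is closest to the target's modeled
    length; ties go to the longer proxy."""
    if len(proxies) == 0:
        raise ValueError("empty proxy pathway")
    confs = proxies.single_conformations()
    n_target = len(target)
    return min(confs, key=lambda c: (abs(len(c) - n_target), -len(c)))
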