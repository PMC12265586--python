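"""Pipeline analyses over folding-pathway intermediates.

Stages implemented here:

* manifest curation (drop conformations flagged for major
  modeled-vs-deposited discrepancies),
* pairwise TM-score comparisons — distinct conformations of the same
  intermediate, the same subsequence across time (consecutive and
  distant), predicted-vs-experimental, proxy-vs-experimental,
* contact order of a conformation,
* two-state pathway statistics: per secondary-structure-element (SSE)
  pair, the snapshot at which a stated fraction of its native contacts
  has formed; a pathway is two-state when all SSE pairs form their
  native contacts within a snapshot window of each other, and the
  two-state fraction is the share of such pathways.

Structure prediction itself is never run here: predicted conformations
are user-supplied files.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .proxy import generate_proxy_intermediates, match_proxy
from .psn import PSNParams
from .structures import Conformation, Manifest, Pathway, map_common_residues
from .superpose import similarity_band, tm_score

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonRecord", "ContactOrderResult", "KineticsReport",
    "curate_manifest", "compare_same_intermediate", "compare_across_time",
    "evaluate_predictions", "evaluate_proxies", "contact_order",
    "two_state_stats", "records_to_frame",
]

COMPARISON_MODES = {
    "same_intermediate", "across_time_consecutive", "across_time_distant",
    "prediction_vs_experiment", "proxy_vs_experiment",
}


@dataclass
class ComparisonRecord:
    protein_id: str
    mode: str
    conf_a: str
    conf_b: str
    n_mapped: int
    tm: float
    band: str

    def __post_init__(self) -> None:
        if self.mode not in COMPARISON_MODES:
            raise ValueError(f"unknown comparison mode {self.mode!r}")
        if not (0 < self.tm <= 1):
            raise ValueError(f"tm out of (0, 1]: {self.tm}")


def _conf_id(c: Conformation) -> str:
    return f"{c.protein_id}/{c.intermediate_index}{c.conformation_label}"


def _record(a: Conformation, b: Conformation, mode: str,
            normalization: str = "common") -> ComparisonRecord:
    res = tm_score(a, b, normalization=normalization)
    return ComparisonRecord(
        protein_id=a.protein_id, mode=mode, conf_a=_conf_id(a),
        conf_b=_conf_id(b), n_mapped=res.n_mapped, tm=res.tm,
        band=similarity_band(res.tm),
    )


_RECORD_COLUMNS = ["protein_id", "mode", "conf_a", "conf_b",
                   "n_mapped", "tm", "band"]


def records_to_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Curation

def curate_manifest(manifest: Manifest) -> tuple[Manifest, dict]:
    """Drop rows flagged as excluded; return the retained manifest plus
    summary counts of conformations and distinct intermediates."""
    t = manifest.table
    retained = Manifest(t[~t["excluded"].astype(bool)].reset_index(drop=True))
    if len(retained) == 0:
        logger.warning("curation retained no conformations")
    summary = {
        "n_conformations_before": manifest.n_conformations,
        "n_conformations": retained.n_conformations,
        "n_intermediates_before": manifest.n_intermediates,
        "n_intermediates": retained.n_intermediates,
        "n_studies": retained.n_studies,
        "n_excluded": manifest.n_conformations - retained.n_conformations,
    }
    return retained, summary


# ---------------------------------------------------------------------------
# Pairwise comparisons

def compare_same_intermediate(conformations: list[Conformation]) -> list[ComparisonRecord]:
    """All unordered pairs among distinct conformations of one intermediate."""
    if len(conformations) < 2:
        raise ValueError("need at least 2 conformations")
    pids = {c.protein_id for c in conformations}
    tidx = {c.intermediate_index for c in conformations}
    if len(pids) > 1 or len(tidx) > 1:
        raise ValueError(
            "conformations must share protein_id and intermediate_index; "
            f"got proteins {sorted(pids)}, intermediates {sorted(tidx)}"
        )
    return [_record(a, b, "same_intermediate")
            for a, b in itertools.combinations(conformations, 2)]


def compare_across_time(pathway: Pathway, distance: str = "consecutive") -> list[ComparisonRecord]:
    """Score the earlier intermediate's subsequence against its later
    conformation, for each ordered time pair (consecutive only, or all)."""
    if distance not in {"consecutive", "all"}:
        raise ValueError("distance must be 'consecutive' or 'all'")
    if len(pathway) < 2:
        raise ValueError("pathway needs at least 2 intermediates")
    records = []
    items = pathway.intermediates
    for i, (t, confs_a) in enumerate(items):
        for j in range(i + 1, len(items)):
            tp, confs_b = items[j]
            if distance == "consecutive" and j != i + 1:
                continue
            mode = ("across_time_consecutive" if j == i + 1
                    else "across_time_distant")
            for a in confs_a:
                for b in confs_b:
                    if len(map_common_residues(a, b)) < 3:
                        logger.warning(
                            "skipped %s vs %s: fewer than 3 shared residues",
                            _conf_id(a), _conf_id(b))
                        continue
                    records.append(_record(a, b, mode))
    return records


def evaluate_predictions(
    experimental: list[Conformation],
    predicted: list[Conformation],
    rank: int = 1,
) -> tuple[list[ComparisonRecord], list[str]]:
    """TM-score of each experimental conformation against its matching
    prediction (matched on protein_id / intermediate_index /
    conformation_label).

    When several ranked predictions share a key, the rank-1 (first
    listed) one is used by default; ``rank`` selects another.
    Experimental conformations without a prediction go into the returned
    gap report rather than raising.
    """
    by_key: dict[tuple, list[Conformation]] = {}
    for p in predicted:
        key = (p.protein_id, p.intermediate_index, p.conformation_label)
        by_key.setdefault(key, []).append(p)
    records, gaps = [], []
    for e in experimental:
        key = (e.protein_id, e.intermediate_index, e.conformation_label)
        cands = by_key.get(key, [])
        if len(cands) < rank:
            gaps.append(_conf_id(e))
            continue
        records.append(_record(e, cands[rank - 1], "prediction_vs_experiment"))
    return records, gaps


def evaluate_proxies(
    native: Conformation,
    k: int,
    experimental: list[Conformation],
) -> list[ComparisonRecord]:
    """Match each experimental conformation to the length-closest proxy
    intermediate of the native and score it over their common residues."""
    proxies = generate_proxy_intermediates(native, k)
    records = []
    for e in experimental:
        if e.modeled_range is not None and native.modeled_range is not None \
                and e.modeled_range[1] > native.modeled_range[1]:
            logger.warning("skipped %s: native covers only up to residue %d",
                           _conf_id(e), native.modeled_range[1])
            continue
        prox = match_proxy(proxies, e)
        if len(map_common_residues(e, prox)) < 3:
            logger.warning("skipped %s: fewer than 3 residues shared with proxy",
                           _conf_id(e))
            continue
        records.append(_record(e, prox, "proxy_vs_experiment"))
    return records


# ---------------------------------------------------------------------------
# Folding-kinetics statistics

@dataclass
class ContactOrderResult:
    """Contact order: average sequence separation |i − j| of residue
    pairs in contact.  Undefined (None) when there are no contacts."""

    n_contacts: int
    absolute_co: float | None
    relative_co: float | None


def _ca_contacts(conf: Conformation, cutoff: float, min_sep: int) -> list[tuple[int, int]]:
    idx = conf.seq_indices
    coords = conf.coords
    out = []
    for i in range(len(conf)):
        for j in range(i + 1, len(conf)):
            if abs(int(idx[j]) - int(idx[i])) < min_sep:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                out.append((int(idx[i]), int(idx[j])))
    return out


def contact_order(conf: Conformation, params: PSNParams | None = None) -> ContactOrderResult:
    """Contact order with a Cα contact rule (default 6.0 Å, |i−j| >= 2,
    excluding backbone neighbors).  relative_co divides by the number of
    residues."""
    if len(conf) < 2:
        raise ValueError("contact order needs at least 2 residues")
    params = params or PSNParams(contact_mode="ca", cutoff=6.0,
                                 min_sequence_separation=2)
    contacts = _ca_contacts(conf, params.cutoff, params.min_sequence_separation)
    if not contacts:
        return ContactOrderResult(n_contacts=0, absolute_co=None, relative_co=None)
    seps = [j - i for i, j in contacts]
    abs_co = float(np.mean(seps))
    return ContactOrderResult(n_contacts=len(contacts), absolute_co=abs_co,
                              relative_co=abs_co / len(conf))


@dataclass
class KineticsReport:
    """Per-pathway native-contact formation times per SSE pair, the
    two-state call per pathway, and the two-state fraction."""

    per_sse_pair_formation_time: list[dict[tuple[str, str], int]]
    is_two_state: list[bool]
    two_state_fraction: float
    sse_pairs_used: list[tuple[str, str]] = field(default_factory=list)


def two_state_stats(
    pathways: list[Pathway],
    native: Conformation,
    sse_annotations: list[tuple[str, int, int]],
    window: int = 1,
    formation_fraction: float = 0.5,
    params: PSNParams | None = None,
) -> KineticsReport:
    """Diagnose two-state vs multi-state folding from pathway snapshots.

    Native contacts are computed once from ``native`` (default Cα 6.0 Å,
    |i−j| >= 2).  For each SSE pair with at least one native inter-SSE
    contact, the formation time in a pathway is the first snapshot index
    at which >= formation_fraction of that pair's native contacts are
    present (the snapshot count if never).  A pathway is two-state iff
    the spread (max − min) of formation times is <= window; the
    two-state fraction is the share of two-state pathways.
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    if len(sse_annotations) < 2:
        raise ValueError("need at least two SSE ranges")
    params = params or PSNParams(contact_mode="ca", cutoff=6.0,
                                 min_sequence_separation=2)
    native_contacts = _ca_contacts(native, params.cutoff,
                                   params.min_sequence_separation)

    def sse_of(seq_index: int) -> str | None:
        for label, lo, hi in sse_annotations:
            if lo <= seq_index <= hi:
                return label
        return None

    pair_contacts: dict[tuple[str, str], list[tuple[int, int]]] = {}
    labels = [lab for lab, _, _ in sse_annotations]
    for la, lb in itertools.combinations(labels, 2):
        pair_contacts[(la, lb)] = []
    for i, j in native_contacts:
        sa, sb = sse_of(i), sse_of(j)
        if sa is None or sb is None or sa == sb:
            continue
        key = (sa, sb) if (sa, sb) in pair_contacts else (sb, sa)
        pair_contacts[key].append((i, j))

    used = [p for p, cs in pair_contacts.items() if cs]
    for p, cs in pair_contacts.items():
        if not cs:
            logger.warning("SSE pair %s has no native contacts; excluded", p)
    if len(used) < 2:
        logger.warning(
            "fewer than 2 SSE pairs with native contacts; every pathway "
            "is trivially two-state")

    all_times: list[dict[tuple[str, str], int]] = []
    flags: list[bool] = []
    for pw in pathways:
        confs = pw.single_conformations()
        T = len(confs)
        snap_contacts = [set(_ca_contacts(c, params.cutoff,
                                          params.min_sequence_separation))
                         for c in confs]
        times: dict[tuple[str, str], int] = {}
        for pair in used:
            need = pair_contacts[pair]
            t_formed = T
            for t, present in enumerate(snap_contacts):
                frac = sum(1 for c in need if c in present) / len(need)
                if frac >= formation_fraction:
                    t_formed = t
                    break
            times[pair] = t_formed
        all_times.append(times)
        spread = (max(times.values()) - min(times.values())) if times else 0
        flags.append(spread <= window)

    return KineticsReport(
        per_sse_pair_formation_time=all_times,
        is_two_state=flags,
        two_state_fraction=sum(flags) / len(flags),
        sse_pairs_used=used,
    )
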