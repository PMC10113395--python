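"""Codon-aligned metagene analysis of ribosome-footprint 5'-end counts.

Footprint 5' ends accumulate at characteristic offsets upstream of a codon
that the ribosome is slow to decode: with ~29-31 nt footprints the A-site
codon sits ~15 nt downstream of the 5' end, the P-site ~12 nt and the
E-site ~9 nt.  Averaging normalized 5'-end counts across all occurrences
of a codon therefore turns codon-specific stalling into a peak at the
corresponding negative offset, visible as an elevated knockout/control
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SITE_OFFSETS",
    "CodonMetagene",
    "PauseCall",
    "codon_occurrences",
    "polycodon_runs",
    "build_tracks",
    "metagene",
    "call_pauses",
]

#: 5'-end-convention ribosome site offsets, nt from the codon's first base.
DEFAULT_SITE_OFFSETS = {-15: "A", -12: "P", -9: "E"}

_VALID_CODON = set("ACGTU")


def _normalize_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid codon: {codon!r}")
    return codon


def codon_occurrences(sequence: str, query_codon: str) -> list[int]:
    """0-based nt positions (codon first base) of in-frame occurrences."""
    query = _normalize_codon(query_codon)
    seq = sequence.upper().replace("U", "T")
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] == query]


def polycodon_runs(
    sequence: str, query_codon: str, min_run: int = 2
) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_run`` consecutive in-frame query codons.

    Returns ``(start_nt, run_length_codons)`` per run.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    occ = codon_occurrences(sequence, query_codon)
    occ_set = set(occ)
    runs = []
    for p in occ:
        if p - 3 in occ_set:
            continue
        length = 1
        while p + 3 * length in occ_set:
            length += 1
        if length >= min_run:
            runs.append((p, length))
    return runs


def build_tracks(
    counts: pd.DataFrame, samples: list[str]
) -> dict[str, np.ndarray]:
    """Long-format counts -> per-transcript (position x sample) arrays."""
    tracks: dict[str, np.ndarray] = {}
    for tid, sub in counts.groupby("transcript_id", sort=True):
        wide = sub.pivot_table(
            index="position", columns="sample", values="count", fill_value=0
        )
        n = int(wide.index.max()) + 1
        arr = np.zeros((n, len(samples)))
        for j, s in enumerate(samples):
            if s in wide.columns:
                arr[wide.index.to_numpy(), j] = wide[s].to_numpy()
        tracks[tid] = arr
    return tracks


@dataclass
class CodonMetagene:
    """Averaged normalized 5'-end profile around occurrences of one codon."""

    codon: str
    window: tuple[int, int]
    offsets: np.ndarray
    profiles: dict[str, np.ndarray]  # group -> mean normalized count per offset
    n_occurrences: int
    n_transcripts: int


@dataclass
class PauseCall:
    """Flagged stalling offsets for one codon."""

    codon: str
    ratios: dict[int, float]        # site offset -> knockout/control ratio
    flagged: dict[int, str] = field(default_factory=dict)  # offset -> site name
    score: float = 1.0
    notes: list[str] = field(default_factory=list)


def metagene(
    cds: dict[str, str],
    counts: pd.DataFrame,
    design: pd.DataFrame,
    query_codon: str,
    window: tuple[int, int] = (-30, 30),
    min_counts: float = 0.1,
    mode: str = "mean",
    anchors: dict[str, list[int]] | None = None,
) -> CodonMetagene:
    """Codon-anchored metagene of normalized footprint 5'-end counts.

    For each transcript passing ``min_counts`` (mean counts/nt across
    samples), each sample's track is normalized by its per-transcript mean;
    windows around every in-frame occurrence of ``query_codon`` are
    extracted (occurrences truncated by the transcript ends are dropped)
    and combined per transcript — averaged across occurrences in ``mean``
    mode, summed in ``cumulative`` mode — then averaged across transcripts
    and, within each group, across samples.

    ``anchors`` overrides the anchor positions per transcript (e.g. run
    starts from :func:`polycodon_runs`).
    """
    if mode not in ("mean", "cumulative"):
        raise ValueError(f"unknown mode: {mode!r}")
    lo, hi = window
    if not lo <= 0 <= hi:
        raise ValueError("window must cover offset 0")
    query = _normalize_codon(query_codon)
    samples = list(design["sample"])
    groups = design.set_index("sample")["group"]
    tracks = build_tracks(counts, samples)

    offsets = np.arange(lo, hi + 1)
    per_group: dict[str, list[np.ndarray]] = {g: [] for g in groups.unique()}
    n_occ_total = 0
    n_tx = 0
    for tid in sorted(tracks):
        arr = tracks[tid]  # positions x samples
        if tid not in cds:
            raise KeyError(f"transcript {tid} has counts but no CDS sequence")
        if arr.mean() < min_counts:
            continue
        anchor_list = (
            anchors.get(tid, []) if anchors is not None
            else codon_occurrences(cds[tid], query)
        )
        n = arr.shape[0]
        usable = [a for a in anchor_list if a + lo >= 0 and a + hi < n]
        if not usable:
            continue
        n_tx += 1
        n_occ_total += len(usable)
        sample_means = arr.mean(axis=0)  # per-sample mean count/nt
        windows = np.stack([arr[a + lo : a + hi + 1, :] for a in usable])
        combined = windows.mean(axis=0) if mode == "mean" else windows.sum(axis=0)
        group_profiles: dict[str, list[np.ndarray]] = {}
        for j, s in enumerate(samples):
            if sample_means[j] <= 0:
                continue
            group_profiles.setdefault(groups[s], []).append(
                combined[:, j] / sample_means[j]
            )
        for g, profs in group_profiles.items():
            per_group[g].append(np.mean(profs, axis=0))

    if n_tx == 0:
        raise ValueError(
            f"no transcript has a qualifying occurrence of codon "
            f"{query_codon.upper().replace('T', 'U')}"
        )
    profiles = {
        g: np.mean(p, axis=0) if p else np.full(len(offsets), np.nan)
        for g, p in per_group.items()
    }
    return CodonMetagene(
        codon=query.replace("T", "U"),
        window=window,
        offsets=offsets,
        profiles=profiles,
        n_occurrences=n_occ_total,
        n_transcripts=n_tx,
    )


def call_pauses(
    metagene_ko: CodonMetagene,
    metagene_ctrl: CodonMetagene | None = None,
    site_offsets: dict[int, str] | None = None,
    threshold: float = 1.5,
    ko_group: str = "knockout",
    ctrl_group: str = "control",
) -> PauseCall:
    """Flag ribosome-site offsets with an elevated knockout/control ratio.

    ``metagene_ctrl`` may be omitted when both group profiles live in one
    :class:`CodonMetagene`.  An offset is flagged when its ratio exceeds
    ``threshold``; a zero control value with non-zero knockout signal is
    flagged as infinite and noted.  ``score`` is the largest flagged ratio
    (1.0 when nothing is flagged).
    """
    site_offsets = site_offsets if site_offsets is not None else DEFAULT_SITE_OFFSETS
    ctrl_source = metagene_ctrl or metagene_ko
    if metagene_ctrl is not None and (
        metagene_ctrl.codon != metagene_ko.codon
        or metagene_ctrl.window != metagene_ko.window
    ):
        raise ValueError("metagenes must share codon and window")
    ko = metagene_ko.profiles[ko_group]
    ctrl = ctrl_source.profiles[ctrl_group]
    call = PauseCall(codon=metagene_ko.codon, ratios={})
    lo = metagene_ko.window[0]
    for off, site in sorted(site_offsets.items()):
        idx = off - lo
        if idx < 0 or idx >= len(ko):
            continue
        if ctrl[idx] > 0:
            ratio = float(ko[idx] / ctrl[idx])
        elif ko[idx] > 0:
            ratio = float("inf")
            call.notes.append(f"zero control signal at offset {off}")
        else:
            ratio = 1.0
        call.ratios[off] = ratio
        if ratio > threshold:
            call.flagged[off] = site
    call.score = max(call.flagged and [call.ratios[o] for o in call.flagged] or [1.0])
    return call
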