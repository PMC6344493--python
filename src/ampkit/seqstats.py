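"""Library and coverage parameter estimation from alignments.

Coverage of a window is defined as (number of read alignment starts in the
window) * R / ws — the single convention shared with segmentation and the
breakpoint-graph likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ContigTable, ReadPairs, StartIndex

WINDOW_SIZES = (10_000, 300)
MIN_CONTIG = 50_000  # exclude tiny (viral) contigs from background sampling


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class SeqStats:
    read_length: float
    insert_mean: float
    insert_sd: float
    proper_fraction: float
    cov_mean: dict = field(default_factory=dict)    # ws -> mu_ws
    cov_median: dict = field(default_factory=dict)  # ws -> theta_ws
    cov_sd: dict = field(default_factory=dict)      # ws -> sigma_ws

    def mu(self, ws: int) -> float:
        return self.cov_mean[ws]

    def theta(self, ws: int) -> float:
        return self.cov_median[ws]

    def sigma(self, ws: int) -> float:
        return self.cov_sd[ws]

    @property
    def max_discordant_span(self) -> float:
        return self.insert_mean + 3 * self.insert_sd

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"read_length={self.read_length:g}\n")
            fh.write(f"insert_mean={self.insert_mean:g}\n")
            fh.write(f"insert_sd={self.insert_sd:g}\n")
            fh.write(f"proper_fraction={self.proper_fraction:g}\n")
            for ws in sorted(self.cov_mean):
                fh.write(f"mu_{ws}={self.cov_mean[ws]:g}\n")
                fh.write(f"theta_{ws}={self.cov_median[ws]:g}\n")
                fh.write(f"sigma_{ws}={self.cov_sd[ws]:g}\n")

    @classmethod
    def from_file(cls, path: str) -> "SeqStats":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.strip().split("=", 1)
                    kv[k] = float(v)
        stats = cls(
            read_length=kv["read_length"],
            insert_mean=kv["insert_mean"],
            insert_sd=kv["insert_sd"],
            proper_fraction=kv["proper_fraction"],
        )
        for k, v in kv.items():
            for pre, target in (
                ("mu_", stats.cov_mean),
                ("theta_", stats.cov_median),
                ("sigma_", stats.cov_sd),
            ):
                if k.startswith(pre):
                    target[int(k[len(pre):])] = v
        return stats


def _sample_windows(contigs, ws, n_windows, blacklist, rng, min_contig):
    """Tiling-grid window sample (without replacement) over eligible contigs."""
    tiles = []
    for tid, (name, length) in enumerate(zip(contigs.names, contigs.lengths)):
        if length < min_contig or length < ws:
            continue
        starts = np.arange(0, (length // ws) * ws, ws)
        bad = np.zeros(len(starts), dtype=bool)
        for (bchrom, bstart, bend) in blacklist:
            if bchrom == name:
                bad |= (starts < bend) & (starts + ws > bstart)
        for s in starts[~bad]:
            tiles.append((tid, int(s)))
    if not tiles:
        return []
    k = min(n_windows, len(tiles))
    idx = rng.choice(len(tiles), size=k, replace=False)
    return [tiles[i] for i in idx]


def window_coverages(index: StartIndex, windows, ws: int, read_len: float):
    return np.array(
        [index.count(tid, s, s + ws) * read_len / ws for tid, s in windows]
    )


def estimate_stats(
    pairs: ReadPairs,
    contigs: ContigTable,
    seed: int = 0,
    n_windows: int = 1000,
    blacklist=(),
    window_sizes=WINDOW_SIZES,
    min_usable: int = 100,
    min_contig: int = MIN_CONTIG,
) -> SeqStats:
    """Estimate SeqStats by random-window sampling.

    Samples ``n_windows`` windows per window size from non-blacklisted
    regions, drops windows with coverage 0 or > 5x the initial median, and
    estimates the proper-pair fraction and insert distribution from pairs
    anchored in the retained 10 kbp windows.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("no alignments")
    rng = np.random.default_rng(seed)
    index = StartIndex(pairs)
    read_len = float(np.mean(pairs.read_len))

    stats = SeqStats(
        read_length=read_len, insert_mean=0.0, insert_sd=0.0,
        proper_fraction=0.0,
    )
    retained_10k = None
    for ws in window_sizes:
        windows = _sample_windows(
            contigs, ws, n_windows, blacklist, rng, min_contig
        )
        if not windows:
            raise InsufficientDataError(f"no sampleable windows at ws={ws}")
        cov = window_coverages(index, windows, ws, read_len)
        med0 = float(np.median(cov))
        keep = (cov > 0) & (cov <= 5 * med0) if med0 > 0 else cov > 0
        if keep.sum() < min_usable:
            raise InsufficientDataError(
                f"only {int(keep.sum())} usable windows at ws={ws}"
            )
        cov = cov[keep]
        stats.cov_mean[ws] = float(np.mean(cov))
        stats.cov_median[ws] = float(np.median(cov))
        stats.cov_sd[ws] = float(np.std(cov))
        if ws == 10_000:
            retained_10k = [w for w, k in zip(windows, keep) if k]

    if retained_10k is None:
        retained_10k = _sample_windows(
            contigs, 10_000, n_windows, blacklist, rng, min_contig
        )
    sel = np.zeros(len(pairs), dtype=bool)
    by_tid = {}
    for tid, s in retained_10k:
        by_tid.setdefault(tid, []).append(s)
    for tid, starts in by_tid.items():
        starts = np.sort(np.asarray(starts))
        loc = np.searchsorted(starts, pairs.pos1, side="right") - 1
        inwin = (loc >= 0) & (pairs.pos1 - starts[np.maximum(loc, 0)] < 10_000)
        sel |= (pairs.tid1 == tid) & inwin
    sub = pairs.subset(sel)
    if len(sub) == 0:
        sub = pairs
    stats.proper_fraction = float(np.mean(sub.proper))
    proper = sub.subset(sub.proper.astype(bool))
    if len(proper):
        spans = proper.outer_span().astype(float)
        stats.insert_mean = float(np.mean(spans))
        stats.insert_sd = float(np.std(spans))
    return stats
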