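"""The file collection: a plain-directory database of signal and feature
files with metadata, plus the precomputed matrix grid cache.

Layout under the collection root::

    registry.json   # entry metadata, keyed by content hash
    files/          # normalized stored copies (signals as bigWig, features as BED)
    cache/          # one binary array per (signal, feature, anchor) + manifest.json

Entries are identified by a stable hash of the file content, so re-adding
identical content is idempotent. The grid cache fingerprint is a pure
function of (signal content hash, feature content hash, anchor fields):
changing any anchoring parameter invalidates the affected entries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .core import FeatureSet, SignalTrack
from .formats import (
    FEATURE_EXTENSIONS,
    SIGNAL_EXTENSIONS,
    convert_to_indexed,
    read_features,
    read_signal,
    write_bed,
)
from .matrix import AnchorSpec, ProfileMatrix, bin_centers_for, compute_matrix
from .motifs import MotifSpec, build_motif_track

log = logging.getLogger("metaplots")


@dataclass
class CollectionEntry:
    id: str
    path: str  # stored location, relative to the collection root
    kind: str  # signal | feature | motif
    format: str  # source format as added
    genome_label: str = ""
    user: str = ""
    comment: str = ""
    added_at: str = ""
    name: str = ""


def _content_id(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


class Collection:
    """A directory-backed registry of tracks and feature files."""

    def __init__(self, root):
        self.root = Path(root)
        self.files_dir = self.root / "files"
        self.cache_dir = self.root / "cache"
        self.registry_path = self.root / "registry.json"
        self.files_dir.mkdir(parents=True, exist_ok=True)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.entries: dict[str, CollectionEntry] = {}
        if self.registry_path.exists():
            with open(self.registry_path) as fh:
                self.entries = {
                    k: CollectionEntry(**v) for k, v in json.load(fh).items()
                }

    def _save(self) -> None:
        with open(self.registry_path, "w") as fh:
            json.dump(
                {k: asdict(v) for k, v in self.entries.items()},
                fh,
                indent=1,
                sort_keys=True,
            )

    # -- adding files ----------------------------------------------------

    def add(
        self,
        path,
        kind: str,
        format: str = "auto",
        genome_label: str = "",
        user: str = "",
        comment: str = "",
    ) -> CollectionEntry:
        """Validate, normalize and store a file; idempotent on content.

        Signal files in text/alignment formats (wiggle, bedGraph, BAM) are
        converted to indexed bigWig at add time; bigWig is stored as-is.
        Feature files are stored as normalized 6-column BED. Nothing is
        persisted if parsing fails.
        """
        path = Path(path)
        if kind not in ("signal", "feature"):
            raise ValueError("kind must be 'signal' or 'feature'")
        entry_id = _content_id(path)
        if entry_id in self.entries:
            return self.entries[entry_id]
        if kind == "signal":
            fmt = (
                format
                if format != "auto"
                else SIGNAL_EXTENSIONS.get(path.suffix.lower(), "")
            )
            track = read_signal(path, format=format)  # validates
            stored = self.files_dir / f"{entry_id}.bw"
            if track.source_format == "bigwig":
                shutil.copyfile(path, stored)
            else:
                convert_to_indexed(track, stored)
        else:
            fmt = (
                format
                if format != "auto"
                else FEATURE_EXTENSIONS.get(path.suffix.lower(), "")
            )
            features = read_features(path, format=format)  # validates
            stored = self.files_dir / f"{entry_id}.bed"
            write_bed(features, stored)
        entry = CollectionEntry(
            id=entry_id,
            path=str(stored.relative_to(self.root)),
            kind=kind,
            format=fmt or "unknown",
            genome_label=genome_label,
            user=user,
            comment=comment,
            added_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            name=path.name,
        )
        self.entries[entry_id] = entry
        self._save()
        return entry

    def add_motif(
        self,
        spec: MotifSpec,
        genome_fasta,
        genome_label: str = "",
        user: str = "",
        comment: str = "",
    ) -> CollectionEntry:
        """Build a motif density track from a genome and store it as bigWig."""
        track = build_motif_track(genome_fasta, spec)
        tag = (
            f"motif|{spec.pattern}|w{spec.window}|"
            f"{'both' if spec.both_strands else 'fwd'}|"
            f"{'perkb' if spec.per_kb else 'raw'}|{_content_id(Path(genome_fasta))}"
        )
        entry_id = hashlib.sha256(tag.encode()).hexdigest()[:12]
        if entry_id in self.entries:
            return self.entries[entry_id]
        stored = self.files_dir / f"{entry_id}.bw"
        convert_to_indexed(track, stored)
        entry = CollectionEntry(
            id=entry_id,
            path=str(stored.relative_to(self.root)),
            kind="motif",
            format="motif",
            genome_label=genome_label,
            user=user,
            comment=comment or f"{spec.pattern} density, window {spec.window}",
            added_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            name=f"{spec.pattern}_density",
        )
        self.entries[entry_id] = entry
        self._save()
        return entry

    # -- lookup ----------------------------------------------------------

    def list_entries(
        self, text: str | None = None, kind: str | None = None, genome: str | None = None
    ) -> list[CollectionEntry]:
        """Filter entries; case-insensitive substring match over name,
        comment and user; stable sort by added_at then id."""
        out = []
        for e in self.entries.values():
            if kind and e.kind != kind:
                continue
            if genome and e.genome_label != genome:
                continue
            if text:
                hay = f"{e.name}\n{e.comment}\n{e.user}".lower()
                if text.lower() not in hay:
                    continue
            out.append(e)
        out.sort(key=lambda e: (e.added_at, e.id))
        return out

    def get_entry(self, entry_id: str) -> CollectionEntry:
        try:
            return self.entries[entry_id]
        except KeyError:
            raise KeyError(f"no collection entry with id {entry_id!r}") from None

    def get_track(self, entry_id: str) -> SignalTrack:
        e = self.get_entry(entry_id)
        if e.kind not in ("signal", "motif"):
            raise ValueError(f"entry {entry_id} is a {e.kind}, not a signal")
        return read_signal(self.root / e.path, format="bigwig")

    def get_features(self, entry_id: str) -> FeatureSet:
        e = self.get_entry(entry_id)
        if e.kind != "feature":
            raise ValueError(f"entry {entry_id} is a {e.kind}, not a feature set")
        return read_features(self.root / e.path, format="bed")

    # -- the precomputed grid -------------------------------------------

    def precompute(
        self, signal_ids: list[str], feature_ids: list[str], anchor: AnchorSpec
    ) -> "GridCache":
        """Compute and persist every signal x feature matrix.

        Pairs already cached under the same fingerprint are skipped. A
        failing pair is logged and does not stop the remaining pairs; the
        returned cache records the failures.
        """
        cache = GridCache(self.cache_dir)
        failures = []
        tracks = {}
        for sid in signal_ids:
            tracks[sid] = None  # lazy-load below
        for sid in signal_ids:
            for fid in feature_ids:
                key = cache.key_for(sid, fid, anchor)
                if cache.has(key):
                    log.info("cache hit for %s x %s", sid, fid)
                    continue
                t0 = time.perf_counter()
                try:
                    if tracks[sid] is None:
                        tracks[sid] = self.get_track(sid)
                    feats = self.get_features(fid)
                    m = compute_matrix(
                        feats,
                        tracks[sid],
                        anchor,
                        signal_label=self.get_entry(sid).name,
                        feature_label=self.get_entry(fid).name,
                    )
                    cache.put(key, sid, fid, anchor, m)
                    log.info(
                        "computed %s x %s (%d x %d) in %.2fs",
                        sid, fid, m.n_features, m.n_bins,
                        time.perf_counter() - t0,
                    )
                except Exception as exc:  # keep going; report at the end
                    log.error("pair %s x %s failed: %s", sid, fid, exc)
                    failures.append((sid, fid, str(exc)))
        cache.failures = failures
        return cache


class GridCache:
    """Persisted (signal, feature, anchor) -> ProfileMatrix store."""

    def __init__(self, cache_dir):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.cache_dir / "manifest.json"
        self.manifest: dict[str, dict] = {}
        self.failures: list[tuple[str, str, str]] = []
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
            # drop entries whose array file disappeared
            self.manifest = {
                k: v
                for k, v in self.manifest.items()
                if (self.cache_dir / v["file"]).exists()
            }

    @staticmethod
    def key_for(signal_id: str, feature_id: str, anchor: AnchorSpec) -> str:
        tag = f"{signal_id}|{feature_id}|{anchor.fingerprint()}"
        return hashlib.sha256(tag.encode()).hexdigest()[:16]

    def has(self, key: str) -> bool:
        return key in self.manifest and (
            self.cache_dir / self.manifest[key]["file"]
        ).exists()

    def put(
        self, key: str, signal_id: str, feature_id: str, anchor: AnchorSpec, m: ProfileMatrix
    ) -> None:
        fname = f"{key}.npy"
        np.save(self.cache_dir / fname, m.values)
        self.manifest[key] = {
            "file": fname,
            "signal_id": signal_id,
            "feature_id": feature_id,
            "signal_label": m.signal_label,
            "feature_label": m.feature_label,
            "feature_ids": m.feature_ids,
            "anchor": anchor.to_dict(),
        }
        self._save()

    def _save(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    def load(self, key: str) -> ProfileMatrix:
        if not self.has(key):
            raise KeyError(f"no cache entry {key}")
        meta = self.manifest[key]
        anchor = AnchorSpec(**meta["anchor"])
        return ProfileMatrix(
            values=np.load(self.cache_dir / meta["file"]),
            bin_centers=bin_centers_for(anchor),
            feature_ids=list(meta["feature_ids"]),
            signal_label=meta["signal_label"],
            feature_label=meta["feature_label"],
            anchor=anchor,
        )

    def load_pair(
        self, signal_id: str, feature_id: str, anchor: AnchorSpec
    ) -> ProfileMatrix:
        return self.load(self.key_for(signal_id, feature_id, anchor))

    def loader(self, anchor: AnchorSpec):
        """A (signal_id, feature_id) -> matrix callable for batch_render."""

        def _load(signal_id, feature_id):
            key = self.key_for(signal_id, feature_id, anchor)
            if not self.has(key):
                raise KeyError((signal_id, feature_id))
            return self.load(key)

        return _load

    def __len__(self) -> int:
        return len(self.manifest)
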