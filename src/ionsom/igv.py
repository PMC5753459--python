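"""IGV batch-script emission for blinded variant review.

Emits the control script a reviewer loads into IGV: for each candidate
locus it opens a fresh session, loads every carrying tumor sample plus
the matched normal, jumps to the locus, sorts reads by base call,
collapses tracks and takes a snapshot named for the locus. Variants are
ordered by genomic position and the script never mentions which
channel(s) called them, keeping the reviewer blinded to caller identity.
Driving IGV itself is out of scope — only the script is produced.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Mapping, Sequence, Tuple

from .core import VariantKey

__all__ = ["render_igv_batch"]


def render_igv_batch(
    variants: Sequence[Tuple[VariantKey, Sequence[str]]],
    alignment_paths: Mapping[str, str],
    normal_lookup: Mapping[str, str],
    out_path=None,
    snapshot_dir: str = "snapshots",
) -> List[str]:
    """Render the batch script; optionally write it to ``out_path``.

    ``variants`` pairs each locus with its carrying tumor samples;
    ``alignment_paths`` maps every sample (tumor and normal) to its
    alignment file; ``normal_lookup`` maps each tumor sample to its
    matched normal. A sample without an alignment path is an error
    naming the sample. Snapshot names are unique per variant allele.
    """
    lines: List[str] = [f"snapshotDirectory {snapshot_dir}"]
    seen_names = set()
    ordered = sorted(variants, key=lambda item: item[0].sort_key())
    for key, samples in ordered:
        if not samples:
            raise ValueError(f"variant {key} has no carrying samples")
        normals = []
        for s in samples:
            if s not in normal_lookup:
                raise KeyError(f"no matched normal for sample {s!r}")
            n = normal_lookup[s]
            if n not in normals:
                normals.append(n)
        lines.append("new")
        for s in list(samples) + normals:
            if s not in alignment_paths:
                raise KeyError(f"no alignment file for sample {s!r}")
            lines.append(f"load {alignment_paths[s]}")
        lines.append(f"goto {key.chrom}:{key.pos}")
        lines.append("sort base")
        lines.append("collapse")
        name = f"{key.chrom}_{key.pos}_{key.ref}_{key.alt}.png"
        if name in seen_names:
            raise ValueError(f"duplicate snapshot name {name}")
        seen_names.add(name)
        lines.append(f"snapshot {name}")
    if out_path is not None:
        Path(out_path).write_text("\n".join(lines) + "\n")
    return lines
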