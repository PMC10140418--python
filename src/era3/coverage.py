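"""Positional read coverage relative to the canonical miRNA 5' end.

Positions are 1-based: position 1 is the canonical first nucleotide,
positions <= 0 are 5' extensions, and positions beyond the canonical
length are 3' tail nucleotides.  Per sample, every isomiR's reads cover
the closed interval [1 + len_5p, L - len_trim + len(tail)] on its own
miRNA's coordinate system (L = canonical length); reads are summed per
position across miRNAs and divided by the sample's total read count,
then sample profiles are averaged within groups (e.g., age bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IsomiRTable, validate_metadata


@dataclass
class CoverageProfiles:
    """Long-format per-group relative coverage plus flank bookkeeping."""

    profile: pd.DataFrame  # columns: group, position, relative_coverage
    canonical_len: int  # reads-weighted modal canonical length
    groups: list[str]

    def wide(self) -> pd.DataFrame:
        return self.profile.pivot(
            index="position", columns="group", values="relative_coverage"
        ).fillna(0.0)


def position_coverage(
    table: IsomiRTable, metadata: pd.DataFrame, group_by: str
) -> CoverageProfiles:
    """Group-averaged relative read coverage per canonical position."""
    md = validate_metadata(metadata)
    if group_by not in md.columns:
        raise ValueError(f"group_by column {group_by!r} not in metadata")
    rec = table.records
    canon_len = rec["mirna_id"].map({k: len(v) for k, v in table.catalog.items()})
    start = 1 + rec["len_5p"]
    end = canon_len - rec["len_trim"] + rec["tail_seq"].str.len()

    pos_min, pos_max = int(start.min()), int(end.max())
    positions = np.arange(pos_min, pos_max + 1)
    reads = rec["reads"].to_numpy(float)
    start_v, end_v = start.to_numpy(), end.to_numpy()

    sample_profiles = {}
    for sample, idx in rec.groupby("sample_id").groups.items():
        loc = rec.index.get_indexer(idx)
        total = reads[loc].sum()
        cov = np.array(
            [
                reads[loc][(start_v[loc] <= p) & (end_v[loc] >= p)].sum()
                for p in positions
            ]
        )
        sample_profiles[sample] = cov / total if total > 0 else cov
    prof = pd.DataFrame(sample_profiles, index=positions)

    groups_series = md[group_by].astype(str)
    rows = []
    kept_groups = []
    for g, members in groups_series.groupby(groups_series).groups.items():
        cols = [s for s in members if s in prof.columns]
        if not cols:
            warnings.warn(f"group {g!r} has no samples with reads; omitted",
                          stacklevel=2)
            continue
        mean_prof = prof[cols].mean(axis=1)
        kept_groups.append(str(g))
        rows.append(
            pd.DataFrame(
                {"group": str(g), "position": positions,
                 "relative_coverage": mean_prof.values}
            )
        )
    if not rows:
        raise ValueError("no non-empty groups")

    # modal canonical length weighted by reads, for flank definitions
    weights = rec.groupby(canon_len)["reads"].sum()
    modal_len = int(weights.idxmax())
    return CoverageProfiles(
        profile=pd.concat(rows, ignore_index=True),
        canonical_len=modal_len,
        groups=kept_groups,
    )


def end_shift_summary(
    profiles: CoverageProfiles,
    reference_group: str,
    flank: str = "3p",
    flank_width: int = 5,
) -> pd.Series:
    """Signed coverage area difference vs. a reference group over one flank.

    For the 3' flank (positions >= canonical_len - flank_width) a negative
    value means the group's 3' ends sit left of (shorter than) the
    reference.  The 5' flank (positions <= 1 + flank_width - 2, i.e., the
    region where 5' variation manifests) should be ~0 when 5' ends are
    stable.
    """
    if reference_group not in profiles.groups:
        raise ValueError(f"reference group {reference_group!r} not found")
    wide = profiles.wide()
    if flank == "3p":
        sel = wide.index >= profiles.canonical_len - flank_width
    elif flank == "5p":
        sel = wide.index <= 1 + flank_width - 2
    else:
        raise ValueError("flank must be '3p' or '5p'")
    sub = wide.loc[sel]
    ref = sub[reference_group]
    out = sub.sub(ref, axis=0).sum(axis=0)
    out.name = f"end_shift_{flank}"
    return out
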