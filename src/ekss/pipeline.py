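"""End-to-end assignment: tables in, per-horse scale results out."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from ekss.bcs import REGIONS, RegionalScores, overall_bcs
from ekss.cohort import normalize_status
from ekss.core import EKSSConfig, assign
from ekss.energy import FeedItem, RequirementConfig, energy_profile
from ekss.errors import ValidationError


def assign_cohort(
    horses: pd.DataFrame,
    scores: pd.DataFrame,
    rations: pd.DataFrame,
    ekss_config: Optional[EKSSConfig] = None,
    req_config: Optional[RequirementConfig] = None,
) -> pd.DataFrame:
    """Run the full scale over a cohort.

    ``horses`` needs horse_id, bw_kg, workload (plus optional tier,
    horse_type, orks); ``scores`` one row per horse per scorer with the six
    regional columns; ``rations`` one row per horse per feed item. Returns
    one row per horse with condition, energy and scale columns, keeping the
    owner label and an agreement flag when ORKS is present.
    """
    ekss_config = ekss_config or EKSSConfig()
    req_config = req_config or RequirementConfig()

    scores_by_horse = {hid: grp for hid, grp in scores.groupby("horse_id")}
    rations_by_horse = {hid: grp for hid, grp in rations.groupby("horse_id")}

    rows = []
    for _, horse in horses.iterrows():
        hid = horse["horse_id"]
        if hid not in scores_by_horse:
            raise ValidationError(f"horse {hid!r} has no condition scores")
        if hid not in rations_by_horse:
            raise ValidationError(f"horse {hid!r} has no ration rows")
        assessments = [
            RegionalScores({r: float(row[r]) for r in REGIONS})
            for _, row in scores_by_horse[hid].iterrows()
        ]
        bcs = overall_bcs(assessments)
        ration = [
            FeedItem(
                name=str(row["feed_name"]),
                kg_per_day=float(row["kg_per_day"]),
                de_density=float(row["de_mcal_per_kg"]),
                cp_density=float(row["cp_g_per_kg"]),
                ad_libitum=bool(row["ad_libitum"]),
                access_hours=float(row["access_hours"]),
            )
            for _, row in rations_by_horse[hid].iterrows()
        ]
        profile = energy_profile(
            bw=float(horse["bw_kg"]),
            ration=ration,
            tier=str(horse.get("tier", "average") or "average"),
            workload=str(horse["workload"]),
            config=req_config,
            horse_type=(
                str(horse["horse_type"])
                if "horse_type" in horse.index and pd.notna(horse.get("horse_type"))
                else None
            ),
        )
        result = assign(bcs, profile, ekss_config)
        row = {
            "horse_id": hid,
            "overall_bcs": bcs.overall_bcs,
            "bcs_rank": bcs.rank,
            "etbf_percent": bcs.etbf_percent,
            "de_m": profile.de_m,
            "dei": profile.dei,
            "dei_percent": profile.dei_percent,
            "cpi_percent": profile.cpi_percent,
            "total_intake_percent": profile.total_intake_percent,
            "b": result.b,
            "c": result.c,
            "rdi5_percent": result.rdi5_percent,
            "ekss_group": result.group,
            "ekss_level": result.level,
        }
        if "orks" in horse.index and pd.notna(horse.get("orks")):
            orks = normalize_status(horse["orks"])
            row["orks"] = orks
            row["agree_flag"] = orks == result.group
        rows.append(row)
    return pd.DataFrame(rows)
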