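"""A synthetic patient-level reconstruction of a published 115-patient
small-mutation dystrophinopathy cohort.

Patient-level data for that cohort are not redistributable, but its printed
summary tables fully determine several joint marginals.  This module
deterministically expands those printed counts into one synthetic row per
patient, so that the cohort-statistics stage can be exercised end to end
and the published associations recomputed from patient-level input.  Only
the tabulated attributes are reconstructed (mutation class, protein domain,
splicing classification grade for nonsense changes, phenotype group,
CpG/PTC/substitution attributes, splice side, dystrophin staining); the
rows are synthetic and carry no variant coordinates.

Reconstructed marginals
-----------------------
* class mixture 60/28/20/6/1 (nonsense/splicing/frameshift/missense/UTR)
  over 115 patients, 66 DMD/IMD + 31 BMD + 18 pending;
* domain x class x severity counts (the domain-distribution table);
* grade x domain x severity among nonsense mutations (the grade table);
* 25/60 CpG nonsense changes (23 C>T, 1 C>A, 1 G>A), transition/transversion
  41/19, PTC types 29 TGA / 15 TAG / 16 TAA, codon-position split 49/4/7;
* frameshift indel kinds 14 deletions / 6 insertions, hidden-PTC types
  11 TGA / 5 TAA / 4 TAG;
* splice sides 14 donor / 14 acceptor, 21 core (+/-1-2) sites;
* 25 biopsies: 8 patchy (7 BMD, 1 pending), 17 absent (15 DMD/IMD, 1 BMD,
  1 pending), with every grade-0 nonsense biopsy staining absent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (mutation_class, domain, severity or None=pending, grade or None) -> count
# Nonsense rows carry the published grade split; pending rows close each
# class to its published total.
_BLOCKS: list[tuple[str, str | None, str | None, int | None, int]] = [
    # nonsense: grade x domain x severity table (53 classifiable)
    ("nonsense", "ABD", "DMD/IMD", 0, 3),
    ("nonsense", "ABD", "DMD/IMD", 1, 1),
    ("nonsense", "RD", "DMD/IMD", 0, 15),
    ("nonsense", "RD", "DMD/IMD", 1, 12),
    ("nonsense", "RD", "BMD", 0, 2),
    ("nonsense", "RD", "BMD", 1, 12),
    ("nonsense", "CRD", "DMD/IMD", 0, 4),
    ("nonsense", "CTD", "DMD/IMD", 0, 4),
    ("nonsense", "RD", None, 0, 4),   # pending nonsense (grade split not printed:
    ("nonsense", "RD", None, 1, 3),   # balanced fill keeps the class total at 60)
    # frameshift (14 classifiable + 6 pending)
    ("frameshift", "ABD", "DMD/IMD", None, 1),
    ("frameshift", "RD", "DMD/IMD", None, 11),
    ("frameshift", "ABD", "BMD", None, 1),
    ("frameshift", "CTD", "BMD", None, 1),
    ("frameshift", "RD", None, None, 6),
    # splicing (25 classifiable + 3 pending)
    ("splicing", "ABD", "DMD/IMD", None, 2),
    ("splicing", "RD", "DMD/IMD", None, 11),
    ("splicing", "CTD", "DMD/IMD", None, 1),
    ("splicing", "ABD", "BMD", None, 2),
    ("splicing", "RD", "BMD", None, 9),
    ("splicing", "RD", None, None, 3),
    # missense (4 classifiable + 2 pending)
    ("missense", "ABD", "DMD/IMD", None, 1),
    ("missense", "ABD", "BMD", None, 2),
    ("missense", "CRD", "BMD", None, 1),
    ("missense", "ABD", None, None, 2),
    # single UTR change
    ("utr", None, "BMD", None, 1),
]


def _expand_blocks() -> pd.DataFrame:
    rows = []
    for cls, domain, severity, grade, n in _BLOCKS:
        for _ in range(n):
            rows.append(
                {
                    "mutation_class": cls,
                    "domain": domain,
                    "severity": severity,
                    "grade": np.nan if grade is None else grade,
                }
            )
    df = pd.DataFrame(rows)
    assert len(df) == 115
    return df


def _assign(df: pd.DataFrame, mask: pd.Series, column: str, values: list) -> None:
    idx = df.index[mask]
    assert len(idx) == len(values), (column, len(idx), len(values))
    df.loc[idx, column] = values


def reference_cohort() -> pd.DataFrame:
    """The deterministic synthetic reconstruction (115 rows)."""
    df = _expand_blocks()
    df["phenotype"] = df["severity"].map({"DMD/IMD": "DMD", "BMD": "BMD"})
    df["phenotype"] = df["phenotype"].fillna("pending")
    # published split of the severe group: 59 DMD + 7 IMD
    severe_idx = df.index[df["severity"] == "DMD/IMD"]
    df.loc[severe_idx[:7], "phenotype"] = "IMD"
    df["truncating"] = df["mutation_class"].isin(["nonsense", "frameshift"])
    for col in ("substitution", "cpg", "ptc_type", "codon_pos", "indel_kind",
                "splice_side", "splice_conservation"):
        df[col] = pd.Series([None] * len(df), dtype="object")

    nons = df["mutation_class"] == "nonsense"
    n_nons = int(nons.sum())
    assert n_nons == 60
    # substitution attributes: 37 C>T + 4 G>A transitions, 19 transversions;
    # CpG 25 = 23 C>T + 1 C>A + 1 G>A
    subs = ["C>T"] * 37 + ["G>A"] * 4 + ["C>A"] * 9 + ["G>T"] * 10
    _assign(df, nons, "substitution", subs)
    df["substitution_class"] = None
    df.loc[nons, "substitution_class"] = [
        "transition" if s in ("C>T", "G>A") else "transversion" for s in subs
    ]
    cpg = [True] * 23 + [False] * 14 + [True] + [False] * 3 + [True] + [False] * 8 + [False] * 10
    _assign(df, nons, "cpg", cpg)
    # PTC types 29 TGA / 15 TAG / 16 TAA and codon positions 49/4/7
    _assign(df, nons, "ptc_type", ["TGA"] * 29 + ["TAG"] * 15 + ["TAA"] * 16)
    _assign(df, nons, "codon_pos", [1] * 49 + [2] * 4 + [3] * 7)

    fs = df["mutation_class"] == "frameshift"
    _assign(df, fs, "indel_kind", ["deletion"] * 14 + ["duplication"] * 6)
    df.loc[fs, "ptc_type"] = ["TGA"] * 11 + ["TAA"] * 5 + ["TAG"] * 4

    sp = df["mutation_class"] == "splicing"
    _assign(df, sp, "splice_side", ["donor"] * 14 + ["acceptor"] * 14)
    _assign(
        df,
        sp,
        "splice_conservation",
        ["core_1_2"] * 21 + ["near_3_5"] * 5 + ["spanning"] * 2,
    )

    # biopsies: every grade-0 nonsense biopsy stains absent; patchy staining
    # occurs in grade-1 nonsense changes (mild or unclassifiable phenotype)
    df["dystrophin_staining"] = "unknown"
    g0_severe = df.index[nons & (df["grade"] == 0) & (df["severity"] == "DMD/IMD")]
    df.loc[g0_severe[:15], "dystrophin_staining"] = "absent"
    g1_bmd = df.index[nons & (df["grade"] == 1) & (df["phenotype"] == "BMD")]
    df.loc[g1_bmd[:7], "dystrophin_staining"] = "patchy"
    df.loc[g1_bmd[7:8], "dystrophin_staining"] = "absent"  # the published exception
    g1_pending = df.index[nons & (df["grade"] == 1) & (df["phenotype"] == "pending")]
    df.loc[g1_pending[:1], "dystrophin_staining"] = "patchy"
    g0_pending = df.index[nons & (df["grade"] == 0) & (df["phenotype"] == "pending")]
    df.loc[g0_pending[:1], "dystrophin_staining"] = "absent"

    # carrier status: 78 determined of 98 submitted (fractions not tabulated
    # per group; a fixed 2:1 carrier split is used for the determined rows)
    carrier = (["carrier", "carrier", "non_carrier"] * 26)[:78]
    df["mother_carrier"] = carrier + ["unknown"] * (115 - 78)

    df.insert(0, "patient_id", [f"R{i + 1:03d}" for i in range(len(df))])
    df["host_exon"] = np.nan  # coordinates are not reconstructable from the tables
    df["provenance"] = "synthetic-reconstruction"
    return df


def grade_phenotype_table(df: pd.DataFrame, domain: str | None = None) -> np.ndarray:
    """2x2 table [[grade0 severe, grade0 mild], [grade1 severe, grade1 mild]]
    restricted to classifiable nonsense patients (optionally one domain)."""
    sub = df[(df["mutation_class"] == "nonsense") & df["severity"].notna()]
    if domain is not None:
        sub = sub[sub["domain"] == domain]
    table = np.zeros((2, 2))
    for g, sev in zip(sub["grade"], sub["severity"]):
        table[int(g), 0 if sev == "DMD/IMD" else 1] += 1
    return table
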