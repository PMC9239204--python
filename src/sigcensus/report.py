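"""Per-genome census tables and per-ecotype aggregates.

The census is a pure function of the classifications: identical inputs give
byte-identical TSV output.  Column order is fixed and documented by
:func:`census_columns`.
"""

from __future__ import annotations

import json
import math
from typing import Optional

import numpy as np
import pandas as pd

from .pipeline import GenomeClassification

_BASE_COLUMNS = [
    "genome_id", "ecotype", "n_genes", "n_chemoreceptors",
]
_COUNT_COLUMNS = [
    "n_HK", "n_HHK", "n_HRR", "n_total_HK", "n_solo", "n_RR",
    "rr_dna_binding", "rr_cdgmp_enzyme", "rr_other_unknown",
    "rr_prop_dna_binding", "rr_prop_cdgmp_enzyme", "rr_prop_other_unknown",
    "total_dgc", "dgc_with_partner", "pde_with_partner", "bifunctional",
    "single_domain", "active_dgc", "n_cdgmp_enzymes",
    "n_ecf", "n_ecf242_clusters", "n_ac", "n_camp_clusters",
    "n_crp_like", "crp_without_cyclase",
    "n_estyk", "n_stas_styk", "n_pp2c", "n_bifunc_pp2c_pkinase", "n_stas",
    "n_qs_present", "n_combined_pathways", "n_atypical_clusters",
]


def census_columns(class_names: list[str]) -> list[str]:
    """The fixed census column order for a given signature configuration."""
    return _BASE_COLUMNS + [f"class_{c}" for c in class_names] + _COUNT_COLUMNS


def _best_status(statuses: list[str]) -> str:
    order = {"full": 3, "half": 2, "partial": 1, "none": 0}
    if not statuses:
        return "none"
    return max(statuses, key=lambda s: order.get(s, 0))


def build_census(
    results: list[GenomeClassification],
    class_names: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Assemble the per-genome census table (one row per genome).

    RR output proportions are computed over proteins with role RR; they are
    NaN (not 0/0) when the genome has no RRs.
    """
    if class_names is None:
        seen = []
        for r in results:
            for a in r.che_assignments:
                if a.class_name and a.class_name not in seen:
                    seen.append(a.class_name)
        class_names = sorted(seen)

    rows = []
    for r in results:
        roles = [t.role for t in r.tcs_roles.values()]
        n_hk = roles.count("HK")
        n_hhk = roles.count("HHK")
        n_hrr = roles.count("HRR")
        n_rr = roles.count("RR")

        rr_pids = {p for p, t in r.tcs_roles.items() if t.role == "RR"}
        cats = [c.category for p, c in r.rr_outputs.items() if p in rr_pids]
        n_dna = cats.count("dna_binding")
        n_enz = cats.count("cdgmp_enzyme")
        n_other = cats.count("other_unknown")

        aux_counts = {}
        for system, col in (
            ("ECF", "n_ecf"), ("AC", "n_ac"), ("CRP_like", "n_crp_like"),
            ("eSTYK", "n_estyk"), ("stas_STYK", "n_stas_styk"), ("PP2C", "n_pp2c"),
            ("bifunctional_PP2C_Pkinase", "n_bifunc_pp2c_pkinase"), ("STAS", "n_stas"),
        ):
            aux_counts[col] = sum(
                1 for c in r.aux_classifications.values() if c.system == system
            )

        row = {
            "genome_id": r.genome.genome_id,
            "ecotype": r.genome.ecotype,
            "n_genes": r.genome.n_genes,
            "n_chemoreceptors": r.n_chemoreceptors,
            "n_HK": n_hk, "n_HHK": n_hhk, "n_HRR": n_hrr,
            "n_total_HK": n_hk + n_hhk + n_hrr,
            "n_solo": sum(1 for v in r.solo.values() if v),
            "n_RR": n_rr,
            "rr_dna_binding": n_dna,
            "rr_cdgmp_enzyme": n_enz,
            "rr_other_unknown": n_other,
            "rr_prop_dna_binding": n_dna / n_rr if n_rr else np.nan,
            "rr_prop_cdgmp_enzyme": n_enz / n_rr if n_rr else np.nan,
            "rr_prop_other_unknown": n_other / n_rr if n_rr else np.nan,
            "total_dgc": r.cdgmp_counts.total_dgc,
            "dgc_with_partner": r.cdgmp_counts.dgc_with_partner,
            "pde_with_partner": r.cdgmp_counts.pde_with_partner,
            "bifunctional": r.cdgmp_counts.bifunctional,
            "single_domain": r.cdgmp_counts.single_domain,
            "active_dgc": r.cdgmp_counts.active_dgc,
            "n_cdgmp_enzymes": len(r.cdgmp_proteins),
            "n_ecf242_clusters": len(r.ecf242),
            "n_camp_clusters": len(r.camp_clusters),
            "crp_without_cyclase": bool(r.crp_without_cyclase),
            "n_qs_present": sum(1 for q in r.qs_reports if q.present),
            "n_combined_pathways": len(r.combined),
            "n_atypical_clusters": len(r.atypical_clusters),
            **aux_counts,
        }
        for cname in class_names:
            statuses = [a.status for a in r.che_assignments if a.class_name == cname]
            row[f"class_{cname}"] = _best_status(statuses)
        rows.append(row)

    df = pd.DataFrame(rows, columns=census_columns(class_names))
    return df.sort_values("genome_id").reset_index(drop=True)


def aggregate_by_ecotype(census: pd.DataFrame) -> pd.DataFrame:
    """Per-ecotype summary: pooled RR output proportions and mean/median
    abundances.

    Proportions are pooled over all RRs in the group (category counts
    summed, then divided), not averaged per genome; groups with zero RRs
    get NaN proportions.  Unknown-ecotype genomes form their own group.
    """
    df = census.copy()
    df["ecotype"] = df["ecotype"].fillna("unknown")
    rows = []
    for ecotype, grp in df.groupby("ecotype", sort=True):
        total_rr = grp["n_RR"].sum()
        row = {
            "ecotype": ecotype,
            "n_genomes": len(grp),
            "total_RR": int(total_rr),
        }
        for cat in ("dna_binding", "cdgmp_enzyme", "other_unknown"):
            pooled = grp[f"rr_{cat}"].sum()
            row[f"prop_{cat}"] = pooled / total_rr if total_rr else np.nan
        for col in ("n_total_HK", "n_RR", "n_cdgmp_enzymes", "n_chemoreceptors",
                    "active_dgc"):
            row[f"mean_{col}"] = grp[col].mean()
            row[f"median_{col}"] = grp[col].median()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_census(census: pd.DataFrame, tsv_path, json_path=None) -> None:
    census.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        records = census.to_dict(orient="records")
        clean = [
            {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in rec.items()}
            for rec in records
        ]
        with open(json_path, "w") as fh:
            json.dump(clean, fh, indent=1, default=_json_default)
            fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
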