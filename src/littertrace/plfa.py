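"""Phospholipid fatty-acid (PLFA) biomarkers and their 13C labeling.

PLFAs are membrane lipids of living microbes; individual fatty acids are
conventional markers for gram-negative bacteria, gram-positive bacteria,
fungi, and a general bacterial pool. PLFAs are measured as fatty-acid
methyl esters (FAMEs), so the methyl carbon added during methanolysis
must be corrected out before the fatty acid's own delta13C is known:

    d13C_FA = ((C_n + 1) * d13C_FAME - d13C_MeOH) / C_n

with C_n the carbon number of the free fatty acid and d13C_MeOH the
methanol signature (default -63 permil).

Two incorporation metrics summarise where litter 13C went:

* between groups — each group's share of the total excess 13C carried by
  labeled fatty acids (sums to 100% across groups when every labeled FA
  is assigned);
* within a group — the share of that group's fatty-acid pool (by
  concentration) that is 13C-enriched relative to controls.

"Enriched" is decided per fatty acid against the matched control
distribution: atom-fraction excess above 3 control SDs, falling back to
an absolute excess threshold when the controls cannot supply an SD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .isotope import delta_to_atom_fraction

__all__ = [
    "DELTA_MEOH_DEFAULT",
    "DEFAULT_MARKER_MAP",
    "GROUPS",
    "FAME_COLUMNS",
    "correct_fame_delta",
    "methylate_delta",
    "assign_groups",
    "flag_enriched",
    "group_metrics",
]

#: delta13C of the methanol used for methylation (permil V-PDB).
DELTA_MEOH_DEFAULT = -63.0

GROUPS = ("gram_negative", "gram_positive", "fungi", "general_bacteria")

#: Conventional marker assignment. The gram-positive list includes the
#: entries "C:17" and "C18:0" as conventionally printed even though
#: C18:0 is sometimes treated as a general marker; override via a user
#: map rather than editing here.
DEFAULT_MARKER_MAP: dict[str, str] = {
    # mono-unsaturated and cyclopropylated
    "C16:1w7c": "gram_negative",
    "C18:1w9c": "gram_negative",
    "C18:1w9t": "gram_negative",
    # iso- and anteiso-branched
    "iC15:0": "gram_positive",
    "aC15:0": "gram_positive",
    "iC16:0": "gram_positive",
    "iC17:0": "gram_positive",
    "C:17": "gram_positive",
    "C18:0": "gram_positive",
    # fungal markers
    "C18:2w6c": "fungi",
    "C18:3w3c": "fungi",
    "C20:5w3c": "fungi",
    # general bacterial markers completing the "total bacteria" sum
    "C14:0": "general_bacteria",
    "C16:0": "general_bacteria",
    "C20:0": "general_bacteria",
    "C15:1": "general_bacteria",
}

FAME_COLUMNS = [
    "texture",
    "depth",
    "treatment",
    "replicate",
    "fa_name",
    "c_n",
    "conc_nmol_g",
    "delta13c_fame_permil",
]


def correct_fame_delta(delta13c_fame, c_n, delta_meoh: float = DELTA_MEOH_DEFAULT):
    """delta13C of the free fatty acid from the measured FAME delta13C."""
    c_n = np.asarray(c_n, dtype=float)
    if np.any(c_n < 2):
        raise ValueError("fatty-acid carbon number must be >= 2")
    delta13c_fame = np.asarray(delta13c_fame, dtype=float)
    out = ((c_n + 1.0) * delta13c_fame - delta_meoh) / c_n
    return out if out.ndim else float(out)


def methylate_delta(delta13c_fa, c_n, delta_meoh: float = DELTA_MEOH_DEFAULT):
    """Forward methylation model: FAME delta13C from the free fatty acid.

    Mass balance over C_n fatty-acid carbons plus one methyl carbon;
    exact inverse of :func:`correct_fame_delta`.
    """
    c_n = np.asarray(c_n, dtype=float)
    out = (c_n * np.asarray(delta13c_fa, dtype=float) + delta_meoh) / (c_n + 1.0)
    return out if out.ndim else float(out)


def assign_groups(fame: pd.DataFrame, marker_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Tag each FAME record with its microbial group.

    Names absent from the map become ``unassigned`` with a warning; they
    still count toward total PLFA but toward no group metric.
    """
    marker_map = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    out = fame.copy()
    out["group"] = out["fa_name"].map(marker_map).fillna("unassigned")
    unknown = sorted(set(out.loc[out["group"] == "unassigned", "fa_name"]))
    if unknown:
        warnings.warn(
            f"fatty acids not in marker map, left unassigned: {', '.join(unknown)}",
            UserWarning,
            stacklevel=2,
        )
    return out


def flag_enriched(
    fame: pd.DataFrame,
    *,
    delta_meoh: float = DELTA_MEOH_DEFAULT,
    n_sd: float = 3.0,
    absolute_excess: float | None = 5e-4,
    match_keys: tuple = ("fa_name",),
) -> pd.DataFrame:
    """Decide per fatty acid whether it carries litter 13C.

    Computes the methanol-corrected delta13C and atom fraction of every
    record, matches each litter-treatment record to the control records
    of the same fatty acid (per ``match_keys``), and flags it enriched
    when its atom-fraction excess over the control mean exceeds
    ``n_sd`` control standard deviations. Where the matched controls
    give no SD (fewer than two records), the ``absolute_excess``
    fallback applies; with no controls and no fallback the call is a
    configuration error.

    Adds columns ``delta13c_fa_permil``, ``atom_fraction``,
    ``af_excess`` and ``enriched``. Control records are never flagged.
    """
    out = fame.copy()
    out["delta13c_fa_permil"] = correct_fame_delta(
        out["delta13c_fame_permil"].to_numpy(), out["c_n"].to_numpy(), delta_meoh
    )
    out["atom_fraction"] = delta_to_atom_fraction(out["delta13c_fa_permil"].to_numpy())

    controls = out[out["treatment"] == "control"]
    if controls.empty and absolute_excess is None:
        raise ValueError(
            "no control records and no absolute enrichment threshold configured"
        )
    stats = (
        controls.groupby(list(match_keys))["atom_fraction"].agg(["mean", "std", "count"])
        if not controls.empty
        else pd.DataFrame(columns=["mean", "std", "count"])
    )

    nat_af = float(delta_to_atom_fraction(-28.0))
    excess = np.zeros(len(out))
    enriched = np.zeros(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        key = tuple(row[k] for k in match_keys)
        key = key[0] if len(key) == 1 else key
        if key in stats.index:
            mean = stats.loc[key, "mean"]
            sd = stats.loc[key, "std"]
        else:
            mean, sd = nat_af, np.nan
        excess[i] = row["atom_fraction"] - mean
        if row["treatment"] == "control":
            continue
        if np.isfinite(sd) and sd > 0:
            enriched[i] = excess[i] > n_sd * sd
        elif absolute_excess is not None:
            enriched[i] = excess[i] > absolute_excess
        else:
            raise ValueError(
                f"no control SD for {key} and no absolute threshold configured"
            )
    out["af_excess"] = excess
    out["enriched"] = enriched
    return out


def group_metrics(
    flagged: pd.DataFrame,
    c_bulk_mg_g: float | pd.Series | None = None,
    *,
    sample_keys: tuple = ("texture", "depth", "replicate"),
) -> pd.DataFrame:
    """Per-group PLFA abundance and the two 13C-incorporation metrics.

    Operates on the litter-treatment records of the output of
    :func:`flag_enriched` after :func:`assign_groups`. For each sample
    (by ``sample_keys``) and each group:

    * ``total_plfa_nmol_g`` — summed FA concentration; divided by
      ``c_bulk_mg_g`` (mg C per g soil) into ``plfa_per_cbulk`` when a
      bulk-C value is supplied;
    * ``rel_incorporation_pct`` — the group's share of the sample's
      total excess 13C carried by enriched FAs, weighting each FA by
      conc * C_n * atom-fraction excess so natural abundance cancels;
    * ``within_group_enriched_pct`` — enriched FA concentration as a
      percentage of the group's total FA concentration.

    Groups with no records in a sample are reported with NaN metrics.
    """
    df = flagged[flagged["treatment"] == "litter"].copy()
    if df.empty:
        raise ValueError("no litter-treatment records to summarise")
    # excess 13C mass per record, nmol 13C g-1 soil (conc is nmol C-FA,
    # i.e. already per FA carbon, hence conc * af_excess; c_n enters via
    # conc being proportional to it for molar FA amounts)
    df["c13_excess"] = df["conc_nmol_g"] * df["af_excess"].clip(lower=0.0)
    records = []
    for keys, sample in df.groupby(list(sample_keys)):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        labeled = sample[sample["enriched"]]
        total_label = labeled["c13_excess"].sum()
        for group in GROUPS + ("unassigned",):
            sub = sample[sample["group"] == group]
            rec = dict(zip(sample_keys, keys))
            rec["group"] = group
            if sub.empty:
                rec.update(
                    total_plfa_nmol_g=np.nan,
                    rel_incorporation_pct=np.nan,
                    within_group_enriched_pct=np.nan,
                    plfa_per_cbulk=np.nan,
                )
                records.append(rec)
                continue
            conc = sub["conc_nmol_g"].sum()
            rec["total_plfa_nmol_g"] = conc
            sub_lab = sub[sub["enriched"]]
            rec["rel_incorporation_pct"] = (
                sub_lab["c13_excess"].sum() / total_label * 100.0
                if total_label > 0
                else np.nan
            )
            rec["within_group_enriched_pct"] = sub_lab["conc_nmol_g"].sum() / conc * 100.0
            if c_bulk_mg_g is not None:
                cb = (
                    float(c_bulk_mg_g)
                    if np.isscalar(c_bulk_mg_g)
                    else float(c_bulk_mg_g[keys if len(keys) > 1 else keys[0]])
                )
                rec["plfa_per_cbulk"] = conc / cb
            else:
                rec["plfa_per_cbulk"] = np.nan
            records.append(rec)
    return pd.DataFrame.from_records(records)
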