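"""End-to-end per-element pipeline producing the master annotation table."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .align import project_to_reference, ref_frame_string
from .dating import date_element
from .element import ERVElement
from .errors import ERVKitError
from .motifs import find_pbs, load_trna_library
from .putein import load_env_reference, reconstruct_putein
from .reference import ReferenceModel
from .structure import annotate_element
from .subgroup import (
    classify_subgroup,
    consensus_columns,
    genotype_key_positions,
    ltr_frame_alignment,
)

logger = logging.getLogger("ervkit")

_FORM_TO_KIND = {
    ("5ltr", "U3-R-U5"): "5p_full",
    ("5ltr", "R-U5"): "5p_RU5",
    ("5ltr", "partial"): "5p_full",
    ("3ltr", "U3-R-U5"): "3p_full",
    ("3ltr", "U3-R"): "3p_U3R",
    ("3ltr", "partial"): "3p_full",
}


@dataclass
class PipelineResult:
    table: pd.DataFrame
    consensus: dict = field(default_factory=dict)  # subgroup -> consensus string
    errors: dict = field(default_factory=dict)  # element id -> stage -> message
    config_hash: str = ""


def _indel_string(indels: list) -> str:
    return ";".join(
        f"{iv.ref_interval.start}{'D' if iv.kind == 'deletion' else 'I'}{iv.length}"
        for iv in indels
    )


def _subgroup_call(model: ReferenceModel, pair, forms):
    calls = {}
    for which, form_attr in (("5ltr", "ltr5_form"), ("3ltr", "ltr3_form")):
        form = getattr(forms, form_attr)
        kind = _FORM_TO_KIND.get((which, form))
        if kind is None:
            calls[which] = None
            continue
        ltr_aln = ltr_frame_alignment(model, pair, which)
        calls[which] = genotype_key_positions(
            ltr_aln,
            ltr_kind=kind,
            pseudo_5p_anchor=model.pseudo_5p_anchor,
            pseudo_3p_anchor=model.pseudo_3p_anchor,
        )
    if calls["5ltr"] is None and calls["3ltr"] is None:
        return None
    return classify_subgroup(calls["5ltr"], calls["3ltr"])


def run_pipeline(
    elements: list,
    model: ReferenceModel,
    config: dict | None = None,
) -> PipelineResult:
    """Project, annotate, classify, date and scan a cohort of elements.

    Stage failures are recorded per element and the pipeline continues;
    identical inputs and configuration produce identical outputs.
    """
    config = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]
    logger.info("ervkit %s pipeline start (%d elements, config %s)",
                __version__, len(elements), cfg_hash)
    rate = config.get("rate", 0.13)
    theta = config.get("theta", 0.20)
    trna_lib = load_trna_library(config.get("trna_library"))
    env_ref, _domains = load_env_reference()
    env_iv = model.landmarks.get("env")

    rows = []
    errors: dict = {}
    per_element: dict = {}
    for el in elements:
        rec: dict = {"id": el.id}
        err: dict = {}
        try:
            pair = project_to_reference(model, el.sequence)
            ann = annotate_element(model, el, pair, theta=theta)
            rec.update(
                label=ann.label,
                ltr5_form=ann.forms.ltr5_form,
                ltr3_form=ann.forms.ltr3_form,
                identity=round(pair.identity, 4),
                not_group_member=pair.not_group_member,
                polyA=ann.signatures.polyA,
                tsd=ann.signatures.tsd or "",
                tt_aaaa=ann.signatures.tt_aaaa,
                indels=_indel_string([i for i in ann.indels if i.length >= 10]),
            )
            for name, (frac, retained) in ann.retention.items():
                rec[f"retention_{name}"] = round(frac, 4)
            per_element[el.id] = (el, pair, ann)
        except ERVKitError as exc:
            err["structure"] = str(exc)
            errors[el.id] = err
            rows.append(rec)
            continue

        try:
            call = _subgroup_call(model, pair, ann.forms)
            if call is None:
                rec["subgroup"] = "unclassifiable"
            else:
                rec["subgroup"] = call.label
                rec["subgroup_n_alt"] = call.n_alt
                rec["subgroup_n_available"] = call.n_available
        except ERVKitError as exc:
            err["subgroup"] = str(exc)
            rec["subgroup"] = "unclassifiable"

        try:
            pbs = find_pbs(pair, model, trna_lib)
            rec["pbs"] = pbs.assignment
        except ERVKitError as exc:
            err["pbs"] = str(exc)

        if err:
            errors[el.id] = err
        rows.append(rec)

    # subgroup consensuses for dating
    consensus: dict = {}
    groups: dict = {}
    for rec in rows:
        eid = rec["id"]
        if eid in per_element and rec.get("subgroup") in ("1", "2", "2A", "2B"):
            sg = "2" if rec["subgroup"].startswith("2") else "1"
            groups.setdefault(sg, []).append(eid)
    for sg, ids in groups.items():
        if len(ids) >= 2:
            cols = [ref_frame_string(model, per_element[i][1]) for i in ids]
            consensus[sg] = consensus_columns(cols, model.sequence)

    for rec in rows:
        eid = rec["id"]
        if eid not in per_element:
            continue
        el, pair, ann = per_element[eid]
        sg = "2" if str(rec.get("subgroup", "")).startswith("2") else "1"
        cons = consensus.get(sg)
        try:
            age = date_element(model, pair, cons, rate=rate)
            rec["age_my"] = round(age.mean_my, 2)
            rec["age_sd"] = round(age.sd_my, 2)
            rec["age_flagged"] = age.flagged
        except ERVKitError as exc:
            errors.setdefault(eid, {})["dating"] = str(exc)

        if env_iv is not None:
            cols = ref_frame_string(model, pair)
            env_nt = cols[env_iv.start - 1 : env_iv.end].replace("-", "")
            if len(env_nt) >= 150:
                try:
                    pt = reconstruct_putein(env_nt, env_ref)
                    rec["putein_length"] = pt.length_aa
                    rec["putein_stops"] = pt.n_internal_stops
                    rec["putein_shifts"] = pt.n_frameshifts
                except ERVKitError as exc:
                    errors.setdefault(eid, {})["putein"] = str(exc)

    table = pd.DataFrame(rows).set_index("id")
    logger.info("pipeline done: %d elements, %d with stage errors",
                len(elements), len(errors))
    return PipelineResult(table=table, consensus=consensus, errors=errors,
                          config_hash=cfg_hash)
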