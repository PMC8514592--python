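"""Mode-of-inheritance determination and Mendelian-violation detection.

Per-variant segregation over a pedigree: de novo (child carries an alt,
both parents called homozygous reference), autosomal recessive, X-linked
recessive and autosomal dominant patterns, with everything else reported
as unknown and absence of the alt in the proband as none. A violation is
a child genotype that no assignment of one transmitted allele per parent
can produce (hemizygous rules apply on chrX/chrY for males); violations
always surface as mode unknown with the reason attached — de novo and
violation are mutually exclusive for the proband record.

Design choices the four-mode vocabulary leaves open: dominant calls
require an affected carrier other than the proband (a lone affected het
child with het unaffected parents stays unknown); a missing parental
genotype makes de novo ineligible rather than asserted; male heterozygous
calls on chrX are treated as genotyping artifacts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (
    Affected,
    AlleleCounts,
    GenotypeCall,
    Individual,
    InheritanceCall,
    InheritanceMode,
    Pedigree,
    Sex,
    is_x_contig,
    is_y_contig,
)
from .region_io import VariantRecord

__all__ = [
    "parse_ped",
    "mode_of_inheritance",
    "mendelian_violation",
    "family_matrix",
]

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFFECTED = {"1": Affected.NO, "2": Affected.YES}


def parse_ped(path: str | Path, proband_id: Optional[str] = None) -> Pedigree:
    """Read a 6-column PED file. The proband defaults to the first
    affected member that has both parents in the file, else the first
    affected member."""
    members: list[Individual] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise ValueError(f"PED line has {len(f)} columns, need 6: {line!r}")
            _, iid, father, mother, sex, pheno = f[:6]
            members.append(
                Individual(
                    id=iid,
                    sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                    affected=_PED_AFFECTED.get(pheno, Affected.UNKNOWN),
                    mother_id=None if mother == "0" else mother,
                    father_id=None if father == "0" else father,
                )
            )
    if proband_id is None:
        affected = [m for m in members if m.affected == Affected.YES]
        with_parents = [m for m in affected if m.mother_id and m.father_id]
        pick = with_parents or affected
        if not pick:
            raise ValueError(f"no affected individual in {path}; name the proband")
        proband_id = pick[0].id
    return Pedigree(members=tuple(members), proband_id=proband_id)


def _gametes(call: GenotypeCall) -> set[int]:
    return {a for a in call.alleles if a is not None}


def mendelian_violation(
    child: GenotypeCall,
    mother: Optional[GenotypeCall],
    father: Optional[GenotypeCall],
    contig: str,
    child_sex: Sex = Sex.UNKNOWN,
) -> tuple[bool, str]:
    """True iff no choice of one transmitted allele per parent can produce
    the child genotype. Missing calls make the trio untestable."""
    calls = (child, mother, father)
    if any(c is None or not c.is_called for c in calls):
        return False, "untestable: missing genotype"
    assert mother is not None and father is not None

    male = child_sex == Sex.MALE
    if is_y_contig(contig):
        if not male:
            return False, "untestable: chrY in non-male"
        alleles = set(child.alleles)
        if len(alleles) > 1:
            return False, "untestable: male chrY heterozygous call"
        ok = alleles <= _gametes(father)
        return (not ok), ("" if ok else "chrY allele not carried by father")

    if is_x_contig(contig) and male:
        alleles = set(child.alleles)
        if len(alleles) > 1:
            return False, "untestable: male chrX heterozygous call"
        ok = alleles <= _gametes(mother)
        return (not ok), ("" if ok else "hemizygous allele not carried by mother")

    m_gametes = _gametes(mother)
    f_gametes = _gametes(father)
    if len(child.alleles) == 1:
        a = child.alleles[0]
        ok = a in m_gametes | f_gametes
        return (not ok), ("" if ok else "allele carried by neither parent")
    target = sorted(child.alleles)  # type: ignore[type-var]
    for m in m_gametes:
        for f in f_gametes:
            if sorted((m, f)) == target:
                return False, ""
    return True, (
        f"child {child.gt_string()} impossible from "
        f"{mother.gt_string()} x {father.gt_string()}"
    )


def _carries_alt(call: Optional[GenotypeCall]) -> Optional[bool]:
    if call is None or not call.is_called:
        return None
    return call.alt_count > 0  # type: ignore[operator]


def mode_of_inheritance(
    genotypes: Mapping[str, GenotypeCall],
    pedigree: Pedigree,
    contig: str,
) -> InheritanceCall:
    """Classify one biallelic variant's segregation in the family."""
    proband = pedigree.proband
    pg = genotypes.get(proband.id)
    if pg is None or not pg.is_called:
        return InheritanceCall(InheritanceMode.UNKNOWN, reason="proband genotype missing")
    if pg.alt_count == 0:
        return InheritanceCall(InheritanceMode.NONE, reason="proband carries no alt allele")

    missing = [
        s for s in pedigree.sample_ids
        if s not in genotypes or not genotypes[s].is_called
    ]
    on_x = is_x_contig(contig)
    male = proband.sex == Sex.MALE
    if on_x and male and pg.is_het and not pg.is_hemizygous:
        return InheritanceCall(
            InheritanceMode.UNKNOWN,
            reason="male chrX heterozygous call (possible genotyping artifact)",
        )

    mother = genotypes.get(proband.mother_id) if proband.mother_id else None
    father = genotypes.get(proband.father_id) if proband.father_id else None
    mother_ok = mother is not None and mother.is_called
    father_ok = father is not None and father.is_called

    # de novo: alt in child, both parents called homozygous reference
    if mother_ok and father_ok and mother.is_hom_ref and father.is_hom_ref:
        return InheritanceCall(
            InheritanceMode.DENOVO,
            reason="proband carries alt; both parents homozygous reference",
        )
    if not (mother_ok and father_ok):
        called_parents = [p for p in (mother, father) if p is not None and p.is_called]
        if all(p.is_hom_ref for p in called_parents):
            reason = "possible denovo, parent uncalled"
        else:
            reason = "parent genotype missing"
        if missing:
            reason += f" (missing: {', '.join(missing)})"
        return InheritanceCall(InheritanceMode.UNKNOWN, reason=reason)

    violated, why = mendelian_violation(pg, mother, father, contig, proband.sex)
    if violated:
        return InheritanceCall(
            InheritanceMode.UNKNOWN, violation=True, reason=f"Mendelian violation: {why}"
        )

    if on_x:
        mother_carrier = mother.is_het
        father_carries = _carries_alt(father)
        if male and pg.is_hom_alt and mother_carrier and father_carries is False:
            return InheritanceCall(
                InheritanceMode.X_LINKED_RECESSIVE,
                reason="hemizygous male proband, carrier mother, non-carrier father",
            )
        if (not male) and pg.is_hom_alt and mother_carrier and father_carries is True:
            return InheritanceCall(
                InheritanceMode.X_LINKED_RECESSIVE,
                reason="homozygous female proband, carrier mother, hemizygous father",
            )
        return InheritanceCall(InheritanceMode.UNKNOWN, reason="no X-linked pattern holds")

    # autosomal recessive: hom-alt child of two het carriers, and no
    # unaffected sibling also hom-alt
    if pg.is_hom_alt and mother.is_het and father.is_het:
        for sib in pedigree.siblings_of(proband.id):
            sg = genotypes.get(sib.id)
            if (
                sib.affected == Affected.NO
                and sg is not None
                and sg.is_called
                and sg.is_hom_alt
            ):
                return InheritanceCall(
                    InheritanceMode.UNKNOWN,
                    reason=f"unaffected sibling {sib.id} also homozygous alternate",
                )
        return InheritanceCall(
            InheritanceMode.AUTOSOMAL_RECESSIVE,
            reason="homozygous alternate proband, both parents heterozygous",
        )

    # autosomal dominant: het proband and carrier status tracks affected
    # status exactly over called samples, with an affected carrier beyond
    # the proband
    if pg.is_het:
        segregates = True
        other_affected_carrier = False
        for member in pedigree.members:
            call = genotypes.get(member.id)
            carries = _carries_alt(call)
            if carries is None or member.affected == Affected.UNKNOWN:
                continue
            if carries != (member.affected == Affected.YES):
                segregates = False
                break
            if carries and member.id != proband.id:
                other_affected_carrier = True
        if segregates and other_affected_carrier:
            return InheritanceCall(
                InheritanceMode.AUTOSOMAL_DOMINANT,
                reason="alt allele segregates with affected status",
            )

    return InheritanceCall(InheritanceMode.UNKNOWN, reason="no inheritance pattern holds")


def _counts_from_call(call: Optional[GenotypeCall]) -> Optional[AlleleCounts]:
    if call is None or call.allele_depths is None or len(call.allele_depths) < 2:
        return None
    ref, alt = call.allele_depths[0], call.allele_depths[1]
    other = 0
    if call.depth is not None:
        other = max(0, call.depth - ref - alt)
    return AlleleCounts(ref_obs=ref, alt_obs=alt, other_obs=other)


def family_matrix(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> pd.DataFrame:
    """One row per (variant, family member): genotype, allele evidence,
    and — on proband rows — the inheritance call. Each child with both
    parents in the pedigree is additionally tested for a violation."""
    rows = []
    for rec in records:
        alt = rec.alts[0] if rec.alts else ""
        moi = mode_of_inheritance(rec.genotypes, pedigree, rec.contig)
        for member in pedigree.members:
            call = rec.genotypes.get(member.id)
            counts = _counts_from_call(call)
            violation = False
            reason = ""
            if member.mother_id and member.father_id:
                violated, why = mendelian_violation(
                    call,
                    rec.genotypes.get(member.mother_id),
                    rec.genotypes.get(member.father_id),
                    rec.contig,
                    member.sex,
                )
                violation = violated
                reason = why
            is_proband = member.id == pedigree.proband_id
            if is_proband:
                # the proband's verdict is the inheritance call's: a de novo
                # pattern is never simultaneously reported as a violation
                violation = moi.violation
            rows.append(
                {
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "sample": member.id,
                    "gt": call.gt_string() if call is not None else "./.",
                    "ref_obs": counts.ref_obs if counts else pd.NA,
                    "alt_obs": counts.alt_obs if counts else pd.NA,
                    "mode": moi.mode.name.lower() if is_proband else "",
                    "violation": violation,
                    "reason": moi.reason if is_proband else reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "sample", "gt",
            "ref_obs", "alt_obs", "mode", "violation", "reason",
        ],
    )
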