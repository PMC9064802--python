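"""Independent brute-force trio classifier working on raw VCF text.

Deliberately shares no code with the package: it re-reads the VCF
line by line, decodes GT/DP/AD/GQ by hand, and applies the
classification rules as literally as possible.  Used to cross-check
``triowes.inheritance`` on randomly generated small cohorts.
"""

from __future__ import annotations


def _parse_sample(fmt: str, cell: str) -> dict:
    keys = fmt.split(":")
    vals = cell.split(":")
    d = dict(zip(keys, vals))
    gt = d.get("GT", ".")
    alleles = gt.replace("|", "/").split("/")
    out = {"alleles": alleles}
    out["dp"] = int(d["DP"]) if d.get("DP", ".") not in (".", "") else 0
    ad = d.get("AD", ".")
    out["ad"] = [int(x) for x in ad.split(",")] if ad not in (".", "") else []
    out["gq"] = int(d["GQ"]) if d.get("GQ", ".") not in (".", "") else 0
    return out


def _carries(sample: dict, alt_index: str) -> bool:
    return alt_index in sample["alleles"]


def _is_hom_ref(sample: dict) -> bool:
    return all(a == "0" for a in sample["alleles"]) and sample["alleles"] != []


def _is_missing(sample: dict) -> bool:
    return any(a == "." for a in sample["alleles"])


def classify_vcf_text(vcf_text: str, proband: str, mother: str, father: str,
                      ab_threshold: float,
                      min_dp: int = 10, min_alt: int = 3,
                      min_parent_gq: int = 50, max_parent_alt: int = 0,
                      ) -> dict[str, str]:
    """Classify every (variant, alt) the proband carries.

    Returns {"chrom:pos:ref:alt": call} with the same label vocabulary
    as the package.  Only proband-carrier records are classified.
    """
    calls: dict[str, str] = {}
    header: list[str] = []
    for line in vcf_text.splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            header = line.lstrip("#").split("\t")
            continue
        fields = line.split("\t")
        row = dict(zip(header, fields))
        fmt = row["FORMAT"]
        p = _parse_sample(fmt, row[proband])
        m = _parse_sample(fmt, row[mother])
        f = _parse_sample(fmt, row[father])
        for ai, alt in enumerate(row["ALT"].split(","), start=1):
            key = f"{row['CHROM']}:{row['POS']}:{row['REF']}:{alt}"
            if _is_missing(p) or not _carries(p, str(ai)):
                continue
            if row["CHROM"].lstrip("chr") in ("Y", "M", "MT"):
                calls[key] = "unresolved"
                continue
            if _is_missing(m) or _is_missing(f):
                calls[key] = "unresolved"
                continue
            m_has, f_has = _carries(m, str(ai)), _carries(f, str(ai))
            if m_has and f_has:
                calls[key] = "transmitted_biparental"
            elif m_has:
                calls[key] = "transmitted_maternal"
            elif f_has:
                calls[key] = "transmitted_paternal"
            else:
                # both parents reference: de novo iff all evidence rules hold
                alt_dp = p["ad"][ai] if len(p["ad"]) > ai else 0
                dp = p["dp"]
                ab_ok = dp > 0 and alt_dp / dp > ab_threshold
                parents_ok = True
                for s in (m, f):
                    if not _is_hom_ref(s):
                        parents_ok = False
                        continue
                    s_alt = s["ad"][ai] if len(s["ad"]) > ai else 0
                    if s["gq"] < min_parent_gq or s_alt > max_parent_alt:
                        parents_ok = False
                if dp >= min_dp and alt_dp >= min_alt and ab_ok and parents_ok:
                    calls[key] = "de_novo"
                else:
                    calls[key] = "unresolved"
    return calls
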