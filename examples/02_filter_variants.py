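"""Run the somatic filter cascade on a small crafted variant batch.

Five tumour records are pushed through the ordered filter stack (read-level
-> somatic-vs-normal -> WGA artifact rules). The verdict log lists exactly
which rule removed each failing record: too few supporting reads, burden at
or below the 5% floor, a contaminated paired normal, and a WGA record with a
homopolymer run of five flanking the variant.
"""

from clonearch import AlleleCountRecord, FilterConfig, filter_cascade
from clonearch.filtering import verdicts_to_frame


def tumour(mut, alt, total=800, **kw):
    fwd = kw.pop("fwd", alt // 2)
    base = dict(
        sample_id="CD34_TP1", source_class="primary_CD34", mutation_id=mut,
        chrom="2", pos=1000, alt_reads=alt, total_reads=total,
        fwd_alt_reads=fwd, rev_alt_reads=alt - fwd,
        flank_left="ACCAAC", flank_right="TGACTG")
    base.update(kw)
    return AlleleCountRecord(**base)


def normal(mut, alt=0, total=800):
    return AlleleCountRecord(
        sample_id="skin", source_class="normal_skin", mutation_id=mut,
        chrom="2", pos=1000, alt_reads=alt, total_reads=total)


records = [
    tumour("SF3B1_K700E", 368),                      # clean somatic het
    tumour("LOWREADS", 2),                           # only 2 supporting reads
    tumour("LOWBURDEN", 32),                         # 4% burden
    tumour("GERMLINE_LIKE", 380),                    # 25% in the paired normal
    tumour("WGA_ARTIFACT", 120, wga=True, flank_left="TAAAAA"),
]
normals = {
    "SF3B1_K700E": normal("SF3B1_K700E"),
    "LOWREADS": normal("LOWREADS"),
    "LOWBURDEN": normal("LOWBURDEN"),
    "GERMLINE_LIKE": normal("GERMLINE_LIKE", alt=200),
    "WGA_ARTIFACT": normal("WGA_ARTIFACT"),
}

passed, verdicts = filter_cascade(records, FilterConfig(), normals=normals)
print(verdicts_to_frame(verdicts).to_string(index=False))
print(f"\n{len(passed)}/{len(records)} records passed; every removal names "
      "the rules it violated, so the cascade is auditable per variant.")
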