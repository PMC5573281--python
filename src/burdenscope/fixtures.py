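"""Worked-example fixture: the neuropeptide-pathway variant table.

Twenty-five variant calls in neuropeptide processing genes from a
restricted-eating cohort (n=38) and a binge-eating cohort (n=55), plus one
previously reported POMC variant listed for context.  Coordinates, alleles,
CADD phred scores, reference-population MAFs and dbSNP identifiers are
carried as printed; each row gets one distinct synthetic carrier, labelled
by cohort section.  Unscored (CADD NA) rows are protein-altering indels or
multi-nucleotide substitutions.

Expected behaviour under the default filter: the UCN and POMC rows are
excluded (previously reported, dbSNP/reference-population records), every
other row qualifies.  That yields 4 qualifying NTS variants, 5 distinct
restricted-eating carriers across NTS/NTSR1, and 4 distinct binge-eating
carriers across GCG/GLP1R.
"""

from __future__ import annotations

from .filtering import AnnotatedVariant

FIXTURE_GROUP_SIZES = {"restricted": 38, "binge": 55}

# gene, chrom, pos, ref, alt, cadd, exac_maf, rs_id, consequence, group
_ROWS = [
    ("NTS",   "12", 86270438, "G", "A", 15.89, None, None, "missense", "restricted"),
    ("NTS",   "12", 86272301, "A", "G", 16.85, None, None, "missense", "restricted"),
    ("NTS",   "12", 86272345, "G", "A", 23.3,  None, None, "missense", "restricted"),
    ("NTS",   "12", 86276089, "G", "A", 29.9,  None, None, "missense", "restricted"),
    ("NTSR1", "20", 61386033, "GCAGGT", "G", None, None, None, "frameshift", "restricted"),
    ("UCN",   "10", 5416075,  "T", "C", 21.3, 5.03e-05, "rs142836326", "missense", "restricted"),
    ("VIP",   "6", 153075342, "A", "G", 22.5,  None, None, "missense", "restricted"),
    ("VIP",   "6", 153077340, "G", "A", 19.39, None, None, "missense", "restricted"),
    ("GCG",   "2", 163003908, "C", "T", 18.38, None, None, "missense", "binge"),
    ("GCG",   "2", 163003961, "GC", "AA", None, None, None, "nonframeshift_indel", "binge"),
    ("GLP1R", "6", 39033595, "GAGGGGAA", "AAGGGGAG", None, None, None, "nonframeshift_indel", "binge"),
    ("GLP1R", "6", 39046934, "A", "G", 28.7,  None, None, "missense", "binge"),
    ("BDNF",  "11", 27680107, "G", "T", 20.557, None, None, "missense", "binge"),
    ("NTRK2", "9", 87325623, "C", "A", 18.764, None, None, "missense", "binge"),
    ("NTRK2", "9", 87549182, "AG", "CC", None, None, None, "nonframeshift_indel", "binge"),
    ("QRFPR", "4", 122301595, "CCA", "ACC", None, None, None, "nonframeshift_indel", "binge"),
    ("UNC80", "2", 210682673, "G", "A", 27.5,  None, None, "missense", "binge"),
    ("UNC80", "2", 210690770, "G", "A", 15.64, None, None, "missense", "binge"),
    ("UNC80", "2", 210699658, "G", "A", 24.6,  None, None, "missense", "binge"),
    ("UNC80", "2", 210737632, "G", "A", 23.6,  None, None, "missense", "binge"),
    ("UNC80", "2", 210745728, "G", "C", 18.51, None, None, "missense", "binge"),
    ("UNC80", "2", 210778652, "G", "A", 32.0,  None, None, "missense", "binge"),
    ("UNC80", "2", 210809854, "C", "A", 27.3,  None, None, "missense", "binge"),
    ("AVP",   "20", 3063808, "G", "A", 21.8,  None, None, "missense", "binge"),
    # previously reported variant, listed for context; the dbSNP record and
    # non-zero reference MAF exclude it from the novel set
    ("POMC",  "2", 25384048, "G", "C", 21.6, 0.00231, "rs28932472", "missense", "binge"),
]


def load_table1_fixture() -> list[AnnotatedVariant]:
    """The packaged neuropeptide-pathway variant table, one distinct
    synthetic carrier per row (R01.. restricted, B01.. binge)."""
    counters = {"restricted": 0, "binge": 0}
    prefixes = {"restricted": "R", "binge": "B"}
    variants = []
    for gene, chrom, pos, ref, alt, cadd, maf, rs, csq, group in _ROWS:
        counters[group] += 1
        carrier = f"{prefixes[group]}{counters[group]:02d}"
        known = frozenset({"dbSNP"}) if rs else frozenset()
        variants.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                genes=(gene,),
                region_class="exonic",
                consequence=csq,
                cadd_phred=cadd,
                known_in=known,
                caller_filters=frozenset(),
                carriers=(carrier,),
                group=group,
                rs_id=rs,
                exac_maf=maf,
            )
        )
    return variants
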