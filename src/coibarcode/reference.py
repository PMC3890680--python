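"""Published reference values for the dreissenid COI RFLP assay.

``REPORTED_GEL_FRAGMENTS`` lists the approximate fragment sizes read off
agarose gels for each enzyme on quagga-mussel (Q) and zebra-mussel (Z)
COI haplotypes.  Gel estimates are approximate; running them through
:func:`coibarcode.rflp.check_conservation` against the 654 bp Folmer
amplicon separates physically consistent patterns from artefacts: the
NlaIV Z5 lane carries an extra ~200 bp partial-digestion band, and the
NlaIII Z sizes over-count the amplicon, so both fail conservation.

``GENBANK_ACCESSIONS`` are published Dreissena COI records usable as an
external cross-check once downloaded (see ``scripts/external_check.py``).
"""

#: Folmer COI amplicon length (bp).
FOLMER_LENGTH = 654

#: (enzyme, lane) -> approximate gel fragment sizes (bp), as reported.
REPORTED_GEL_FRAGMENTS: dict[tuple[str, str], tuple[int, ...]] = {
    ("HinfI", "Q"): (73, 581),
    ("HinfI", "Z"): (31, 101, 114, 195, 213),
    ("NlaIII", "Q"): (193, 461),
    ("NlaIII", "Z"): (193, 319, 335),
    ("NlaIV", "Q"): (70, 79, 211, 294),
    ("NlaIV", "Z1/Z2"): (91, 120, 150, 293),
    ("NlaIV", "Z3/Z4"): (91, 150, 413),
    ("NlaIV", "Z5"): (91, 150, 200, 413),
    ("ScrFI", "Q"): (42, 53, 120, 171, 268),
    ("ScrFI", "Z"): (95, 152, 407),
}

#: Lanes whose sizes cannot come from a complete digest of 654 bp.
KNOWN_ARTEFACT_LANES = {("NlaIV", "Z5"), ("NlaIII", "Z")}

#: Published Dreissena COI GenBank accessions (quagga, zebra and
#: congeners) for the optional external cross-check.
GENBANK_ACCESSIONS = (
    "DQ840122", "DQ840125", "DQ840123", "DQ840121", "EF414493",
    "U47653", "AF474404", "EU484441", "EU484437", "EU484448",
    "EU484444", "AM748997", "AM748986", "AM748977", "U47651",
    "U47650", "DQ840132", "EF080861", "AF495877", "AF479637",
    "AM748999",
)
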