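"""Fixed sequence parts of the pegRNA-sensor cloning cassette.

The full oligo is assembled as::

    adapter5 - spacer(21 nt) - scaffold - 3' extension - motif3 - sensor(60 nt) - adapter3

``adapter5`` carries the single designated Esp3I site (CGTCTC) and ``adapter3``
the single designated EcoRI site (GAATTC) used for Golden-Gate-style cloning;
the variable region between them must contain neither site on either strand.
"""

# Amplification adapters; adapter3 is the reverse primer's reverse complement
# so the assembled record reads 5'->3' on the top strand.
ADAPTER5 = "CATAGCGTACACGTCTCACACCG"
ADAPTER3 = "GAATTCTAGATCCGGTCGTCAACGGCAC"

# "Flip + extension" SpCas9 scaffold. The unmodified scaffold contains a TTTT
# run that would act as a U6 terminator, so the polyT-free variant is the only
# usable default for a U6-transcribed cassette.
SCAFFOLD = (
    "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCA"
    "ACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

# tevopreQ1 pseudoknot appended 3' of the extension (epegRNA motif).
MOTIF3 = "CGCGGTTCTATCTAGTTACGCGTTAAACCAACTAGAA"

ECORI_SITE = "GAATTC"
ESP3I_SITE = "CGTCTC"

DEFAULT_PARTS = {
    "adapter5": ADAPTER5,
    "scaffold": SCAFFOLD,
    "motif3": MOTIF3,
    "adapter3": ADAPTER3,
}
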