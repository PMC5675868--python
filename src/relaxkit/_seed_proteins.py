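"""Fixed synthetic seed query proteins for the planted-homolog generators.

These are *synthetic* stand-ins, not real plasmid proteins: a 400-residue
random-composition relaxase-sized query, and 79- and 147-residue auxiliary
queries whose N-termini carry the strand-helix-helix composition produced by
:func:`relaxkit.synth.generate_rhh_protein` (sizes match the small/large
auxiliary proteins of relaxosome operons).  They were drawn once from a
fixed RNG and frozen here so that planted replicons, query FASTA files and
closed-loop tests all agree; users mining real data supply their own query
FASTA instead.  The two auxiliary queries use disjoint residue pools for
their motif cores so the synthetic families stay separable under homology
search.
"""

RELAXASE_SEED = (
    "MQCDMYYKRWTRQYQFMGDEDDWDYQHAPTRVSWRCQNVPLVAYVTKICVDRISVLEKGAIKHLRCEQ"
    "QAWQMGMMQTSFTKCDPGEMACWCTFMYDFYAEGQEPNITWRLERYKHGLLFKFGVQCYPDDQDMYEV"
    "KRSRSQQFLRTRMRYFPPGSMPNIMCLKYTPGKCGLCLPPDYMEEFKWRNQKLPYDCGMDHNHARREV"
    "FFRRRGCLFTEMIMKHKRSTRIPKQIPHLEFYCMPVPVILEWQFLTSFTEIWIPSDHQCDKTWVEVDQ"
    "SKFKQFSTAKFKHHYVQQHWMQCFPLTYACNNYDSFYEHMKFNKVSNCGILEKSHYYTVCLIKSAYCP"
    "PSINCCPRPPSYFTYPDWFSISHTPCCKTERGWVKQCQYYEEEWVYEESIIIIMNLNTRV"
)

AUX1_SEED = (
    "MIVVIIIVNGNGALEALLLLERKKPPPGPKKLAELALEEAEQLYDATDAMSIKNTLGSLLTMDHMDIH"
    "DRPPKPKNHTM"
)

AUX2_SEED = (
    "MYYFYFFYGGNGMMKKKKKMMKRRNGPNGRRMKKKMMKKMMCSVCCQNLAKQQQRVPAHPRVHQSTVE"
    "CLQWVHADMAEENICYINMDPNNSLCEYGSDQGNSPPPWTAAMGKNRYLWHEFMSKMMKICTRCQYCC"
    "MMDLKSSINQM"
)

SEED_QUERIES = {
    "relaxase_query": RELAXASE_SEED,
    "aux1_query": AUX1_SEED,
    "aux2_query": AUX2_SEED,
}
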