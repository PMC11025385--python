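>MANEA_ref_synthetic synthetic stand-in on human MANEA (Q5SRI9) coordinates; canonical GH99 motif residues planted at 189, 195-199, 222-226, 323, 404-407
MLLVKLQLIKYCEGQEVGSAEFITHKLKMLDAQRRQKESVECFLSKQYLPFSPGAIWNSM
FDAQKGQGPQLGVTPLGFTNAIQTQYLTIPVNQLGSYLNGEKQRLQIESQPRSVQVKLQM
HKISLEELVRAIDYLSSATGDTTTTVQCAPGMSQVKWLYISGAPRVLGSVGFGRNTIEEE
ESFKSRTCYLGPPTDENGESHLLLSETNPPKQKDASGCPGLHIEPYMVKVNRRGGSAKVE
LKKLGGRSYNNVATVPQSKPIEYLEDFRLLVSEIVSRPSVSVVNYAFTGTMMLNVFTENF
DPKYTEQALAIEETPMHLKESRYAYEAKKDVCGLFGDHIFVVVIDLEIKPKEVGVCCSEA
GVAGLKQPFWVGRDPILVSQVEPGPIIGLVDTADTYEDPSRLDEWHERDAVLSSMSGESE
EPESVDDGAREMSKMSEKTRKIIIGPECLSTDGQAEQTDVRA
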