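# Annotation substrings (case-insensitive) that disqualify a protein from
# the non-lysin negative set.  Seeded from the lysin-related functional
# vocabulary of phage annotation databases; not authoritative — override
# with your own list for production dataset builds.
peptidase
amidase
lysozyme
deacetylase
endolysin
lysin
glucosaminidase
muramidase
transglycosylase
glycosidase
glycoside hydrolase
spanin
holin
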