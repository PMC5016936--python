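>env_reference_protein
MHQYKKWMGSIPEHYMHVLKWVSGDLALVLFSMLQRGAGLCAKQMTLPFDIRLRWIMKMTIRALYVSAVI
RIMNMHCHKQFLHLMLNICDDTYGPHTNNSDGGGWKDYTRFKHTPSHQVREPEMYHCQNCYHLFVRFEIR
FNHPSQITKSIGMGCATHCMRYNHYGAGHHYSKEHCHDCAVYTDFCWICAECEAGAFQALMWEDCQIAEH
VNRDKLDSISIWTACIQTQFNYMQTCVCCQIMGLIISCGIEIWEAKPIFIWREYMANWLWWDGQTTNTIW
HWETPPWGMFHAYCWQEEHEDNHWKWPFGSRRNRKNRFSQPWDRSMNMWYWAWIMLQVETWHRRYEHFPF
THEKPHPFNGSFITQMQEMMPCKFDPDQETHSPHYGCCLDKGRACCWNSLQNRRALDLLFAERGGTWHWQ
IIENHCKGAFQYRTGRRMFSQTRRGGHCPQCADVHVNSVVQTFQGFYVFISMYTLHRPHPKAYLKDKNCD
SQYCESAAPLQNKMGKSTNSKMYPPQVENWCTHIMKLSSQVPRQMYQD
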