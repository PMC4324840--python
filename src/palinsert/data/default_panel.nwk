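((((cow,zebu),buffalo),eland),((((goat,ibex),sheep),(gazelle,(wildebeest,addax))),tibetan_antelope),((red_deer,spotted_deer),giraffe));
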