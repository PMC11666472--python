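lemma	word_class	category	gloss	log_freq
schaatser	noun	sport	skater
wielrenner	noun	sport	cyclist
voetballer	noun	sport	footballer
surfer	noun	sport	surfer
zwemmer	noun	sport	swimmer
atleet	noun	sport	athlete
turner	noun	sport	gymnast
bokser	noun	sport	boxer
cellist	noun	music	cellist
saxofonist	noun	music	saxophonist
violist	noun	music	violinist
gitarist	noun	music	guitarist
pianist	noun	music	pianist
drummer	noun	music	drummer
muzikant	noun	music	musician
zanger	noun	music	singer
vasthouden	verb	contact	hold
aanvallen	verb	contact	attack
wegduwen	verb	contact	push_away
krabben	verb	contact	scratch
schoppen	verb	contact	kick
grijpen	verb	contact	grab
trappen	verb	contact	kick2
knijpen	verb	contact	squeeze
opmerken	verb	perception	notice
zien	verb	perception	see
ontdekken	verb	perception	discover
begluren	verb	perception	peep
herkennen	verb	perception	recognize
bekijken	verb	perception	look
aanstaren	verb	perception	stare
waarnemen	verb	perception	perceive
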