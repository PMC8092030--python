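# Plutchik basic-emotion seed terms, one emotion<TAB>term per line
anger	angry
anger	furious
anger	rage
anger	outraged
anger	mad
anger	irate
sadness	sad
sadness	grief
sadness	sorrow
sadness	unhappy
sadness	depressed
sadness	miserable
joy	happy
joy	joyful
joy	delighted
joy	cheerful
joy	glad
joy	elated
trust	trust
trust	confidence
trust	faith
trust	reliable
trust	secure
trust	assured
anticipation	anticipation
anticipation	expectation
anticipation	eager
anticipation	hopeful
anticipation	awaiting
anticipation	optimistic
fear	fear
fear	scared
fear	afraid
fear	terrified
fear	panic
fear	anxious
disgust	disgust
disgust	disgusted
disgust	gross
disgust	revolting
disgust	sickening
disgust	repulsed
surprise	surprised
surprise	astonished
surprise	amazed
surprise	shocked
surprise	startled
surprise	stunned
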