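glycine and serine metabolism	synthetic stand-in compound set	glycine	serine	methionine	betaine	sarcosine
ammonia cycle	synthetic stand-in compound set	ornithine	citrulline	arginine	glutamate	glutamine
urea cycle	synthetic stand-in compound set	arginine	ornithine	citrulline	argininosuccinic acid	urea
alanine metabolism	synthetic stand-in compound set	alanine	glutamate	pyruvate
methionine metabolism	synthetic stand-in compound set	methionine	glycine	serine	homocysteine
carnitine metabolism	synthetic stand-in compound set	free carnitine	acetylcarnitine	propionylcarnitine	butyrylcarnitine	valerylcarnitine	hexanoylcarnitine
beta-oxidation of long-chain fatty acids	synthetic stand-in compound set	hexadecanoylcarnitine	octadecanoylcarnitine	tetradecanoylcarnitine	lignoceroylcarnitine	hexacosanoylcarnitine	arachidoylcarnitine
branched-chain amino acid metabolism	synthetic stand-in compound set	leucine	isoleucine	valine	tiglylcarnitine
glutathione metabolism	synthetic stand-in compound set	glutamate	glycine	cysteine
phospholipid metabolism	synthetic stand-in compound set	lysophosphatidylcholine C20:0	lysophosphatidylcholine C22:0	lysophosphatidylcholine C24:0	lysophosphatidylcholine C26:0	choline
purine metabolism	synthetic stand-in compound set	adenosine	deoxyadenosine	hypoxanthine
tyrosine metabolism	synthetic stand-in compound set	tyrosine	phenylalanine	succinylacetone
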