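substrate	test_type	model_prediction	experimental
glucose	carbon	+	+
cellobiose	carbon	+	+
sorbitol	carbon	+	-
fructose	carbon	+	+
galactose	carbon	+	-
maltose	carbon	+	+
mannose	carbon	+	-
sucrose	carbon	+	+
xylose	carbon	+	-
arabinose	carbon	-	-
rhamnose	carbon	-	-
pyruvate	carbon	-	-
succinate	carbon	-	-
citrate	carbon	-	-
glycerol	carbon	-	-
pectin	carbon	-	-
cellulose	carbon	+	+
lignocellulose	carbon	+	+
acetate	carbon	-	-
fumarate	carbon	-	-
n-acetyl-glucosamine	carbon	-	-
lactate	carbon	-	-
maltodextrin	carbon	+	+
methanol	carbon	-	-
oxaloacetate	carbon	-	-
xylan	carbon	+	+
ethanol	carbon	-	-
malate	carbon	-	-
formate	carbon	-	-
raffinose	carbon	+	+
phenylalanine	carbon	-	-
arginine	carbon	-	-
leucine	carbon	-	-
proline	carbon	-	-
serine	carbon	-	-
threonine	carbon	-	-
pyridoxine	vitamin	+	+
p-aminobenzoic acid	vitamin	-	-
biotin	vitamin	-	+
cyanocobalamin	vitamin	+	+
riboflavin	vitamin	+	+
folic acid	vitamin	+	+
pantothenate	vitamin	+	+
nicotinic acid	vitamin	+	+
thiamin	vitamin	+	+
heme	vitamin	-	-
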