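variant,canonical
dog,dog
cat,cat
fish,fish
bird,bird
horse,horse
cow,cow
pig,pig
sheep,sheep
chicken,chicken
duck,duck
rabbit,rabbit
mouse,mouse
tiger,tiger
lion,lion
elephant,elephant
monkey,monkey
bear,bear
wolf,wolf
fox,fox
deer,deer
snake,snake
frog,frog
turtle,turtle
goat,goat
donkey,donkey
camel,camel
giraffe,giraffe
zebra,zebra
kangaroo,kangaroo
panda,panda
koala,koala
squirrel,squirrel
rat,rat
hamster,hamster
bat,bat
owl,owl
eagle,eagle
hawk,hawk
sparrow,sparrow
pigeon,pigeon
crow,crow
swan,swan
goose,goose
peacock,peacock
parrot,parrot
penguin,penguin
ostrich,ostrich
flamingo,flamingo
seagull,seagull
woodpecker,woodpecker
shark,shark
whale,whale
dolphin,dolphin
octopus,octopus
squid,squid
crab,crab
lobster,lobster
shrimp,shrimp
jellyfish,jellyfish
starfish,starfish
seal,seal
walrus,walrus
otter,otter
beaver,beaver
hedgehog,hedgehog
mole,mole
ferret,ferret
weasel,weasel
badger,badger
raccoon,raccoon
skunk,skunk
porcupine,porcupine
armadillo,armadillo
sloth,sloth
anteater,anteater
chimpanzee,chimpanzee
gorilla,gorilla
orangutan,orangutan
baboon,baboon
lemur,lemur
hippopotamus,hippopotamus
rhinoceros,rhinoceros
buffalo,buffalo
bison,bison
moose,moose
elk,elk
reindeer,reindeer
antelope,antelope
gazelle,gazelle
leopard,leopard
cheetah,cheetah
jaguar,jaguar
panther,panther
lynx,lynx
hyena,hyena
jackal,jackal
coyote,coyote
crocodile,crocodile
alligator,alligator
lizard,lizard
gecko,gecko
iguana,iguana
chameleon,chameleon
salamander,salamander
newt,newt
toad,toad
ant,ant
bee,bee
wasp,wasp
butterfly,butterfly
moth,moth
beetle,beetle
ladybug,ladybug
dragonfly,dragonfly
grasshopper,grasshopper
cricket,cricket
cockroach,cockroach
mosquito,mosquito
fly,fly
spider,spider
scorpion,scorpion
centipede,centipede
millipede,millipede
earthworm,earthworm
snail,snail
slug,slug
clam,clam
oyster,oyster
mussel,mussel
eel,eel
salmon,salmon
tuna,tuna
trout,trout
carp,carp
goldfish,goldfish
catfish,catfish
cod,cod
herring,herring
sardine,sardine
anchovy,anchovy
mackerel,mackerel
swordfish,swordfish
stingray,stingray
seahorse,seahorse
pufferfish,pufferfish
angelfish,angelfish
heron,heron
crane,crane
stork,stork
pelican,pelican
albatross,albatross
falcon,falcon
vulture,vulture
condor,condor
raven,raven
magpie,magpie
cuckoo,cuckoo
nightingale,nightingale
canary,canary
finch,finch
robin,robin
bluejay,bluejay
cardinal,cardinal
hummingbird,hummingbird
kingfisher,kingfisher
turkey,turkey
pheasant,pheasant
quail,quail
partridge,partridge
dove,dove
mule,mule
llama,llama
alpaca,alpaca
yak,yak
boar,boar
warthog,warthog
meerkat,meerkat
mongoose,mongoose
chinchilla,chinchilla
gerbil,gerbil
platypus,platypus
echidna,echidna
opossum,opossum
wombat,wombat
dingo,dingo
emu,emu
kiwi,kiwi
toucan,toucan
macaw,macaw
cockatoo,cockatoo
budgerigar,budgerigar
swallow,swallow
tapir,tapir
okapi,okapi
manatee,manatee
narwhal,narwhal
orca,orca
porpoise,porpoise
barracuda,barracuda
piranha,piranha
puppy,dog
doggy,dog
kitten,cat
kitty,cat
bunny,rabbit
hen,chicken
rooster,chicken
hippo,hippopotamus
rhino,rhinoceros
chimp,chimpanzee
croc,crocodile
gator,alligator
piglet,pig
lamb,sheep
foal,horse
pony,horse
budgie,budgerigar
killer whale,orca
tomcat,cat
ewe,sheep
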